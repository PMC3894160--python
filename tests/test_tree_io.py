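"""Topology handling and file formats: Newick, FASTA, branch tables."""

import numpy as np
import pytest

from ercov import (
    AlignmentError,
    DuplicateRecordError,
    FormatError,
    GeneSet,
    NewickParseError,
    Phylogeny,
    TooFewSpeciesError,
    read_branch_table,
    read_fasta_alignment,
    read_gene_set,
    read_newick,
    write_branch_table,
    write_newick,
)
from ercov.io import decode_branch_id, encode_branch_id
from ercov.simulate import random_topology

from conftest import make_vector


class TestNewick:
    def test_branch_counts_unrooted(self):
        t = Phylogeny.from_newick("(A:0.1,B:0.2,(C:0.3,D:0.4):0.05);")
        assert t.n_leaves == 4
        assert t.n_branches == 2 * 4 - 3

    def test_two_leaf_tree_is_degenerate_but_readable(self):
        t = Phylogeny.from_newick("(A:0.1,B:0.2);")
        assert t.n_leaves == 2
        assert t.n_branches == 1
        # below the minimum usable size for any pruning-based analysis
        with pytest.raises(TooFewSpeciesError):
            t.prune({"A", "B"})

    def test_twelve_leaf_tree_has_21_branches(self, tree12):
        assert tree12.n_branches == 2 * 12 - 3

    def test_rooted_input_is_unrooted(self):
        rooted = "((A:0.1,B:0.2):0.03,(C:0.3,D:0.4):0.02);"
        t = Phylogeny.from_newick(rooted)
        assert t.n_branches == 5  # root suppressed, incident lengths summed
        internal = [b for b in t.branch_ids if len(b) == 2][0]
        assert t.branch_lengths[internal] == pytest.approx(0.05)

    @pytest.mark.parametrize(
        "bad", ["((A,B);", "(A,A,B);", "", "(A);"]
    )
    def test_parse_errors(self, bad):
        with pytest.raises(NewickParseError):
            Phylogeny.from_newick(bad)

    def test_round_trip_preserves_branches_and_lengths(self, tmp_path):
        t = random_topology(9, seed=5)
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        t2 = read_newick(p)
        assert t.equals(t2)

    def test_branch_ids_stable_across_rereads(self):
        s = "(A:0.1,B:0.2,(C:0.3,(D:0.1,E:0.2):0.2):0.05);"
        a = Phylogeny.from_newick(s)
        b = Phylogeny.from_newick(s)
        assert a.branch_ids == b.branch_ids


class TestPrune:
    def test_identity_prune(self, tree12):
        sub, mapping = tree12.prune(tree12.leaf_names)
        assert sub.same_topology(tree12)
        assert all(mapping[b] == frozenset([b]) for b in sub.branch_ids)

    def test_prune_12_to_5_has_7_branches(self, tree12):
        keep = sorted(tree12.leaf_names)[:5]
        sub, _ = tree12.prune(keep)
        assert sub.n_branches == 2 * 5 - 3

    def test_hand_computed_suppression(self, tree4):
        # drop B: the A pendant absorbs the internal branch (0.1 + 0.05)
        sub, mapping = tree4.prune({"A", "C", "D"})
        lens = sub.branch_lengths
        assert lens[frozenset({"C", "D"})] == pytest.approx(0.15)
        assert lens[frozenset({"C"})] == pytest.approx(0.3)
        assert lens[frozenset({"D"})] == pytest.approx(0.4)
        merged = mapping[frozenset({"C", "D"})]
        assert len(merged) == 2  # A pendant + internal branch

    def test_path_lengths_preserved_under_pruning(self, rng):
        t = random_topology(10, seed=11)
        sp, d = t.leaf_distances()
        keep = list(rng.choice(sp, size=6, replace=False))
        sub, _ = t.prune(keep)
        sp2, d2 = sub.leaf_distances()
        idx = [sp.index(s) for s in sp2]
        assert np.allclose(d2, d[np.ix_(idx, idx)])

    def test_prune_composition_matches_intersection(self, rng):
        t = random_topology(12, seed=23)
        leaves = sorted(t.leaf_names)
        for trial in range(20):
            big = set(rng.choice(leaves, size=9, replace=False))
            small = set(list(big)[:5])
            via_two = t.prune(big)[0].prune(small)[0]
            direct = t.prune(small)[0]
            assert via_two.same_topology(direct)
            assert via_two.equals(direct, rtol=1e-12)

    def test_too_few_species(self, tree12):
        with pytest.raises(TooFewSpeciesError):
            tree12.prune(sorted(tree12.leaf_names)[:2])


class TestFasta:
    def test_read_matches_hand_parse(self, tmp_path):
        p = tmp_path / "g1.fasta"
        p.write_text(">dmel extra stuff\nMKV-A\n>dsim\nMKVLA\n>dyak\nMKILA\n")
        aln = read_fasta_alignment(p)
        assert aln.n_rows == 3
        assert aln.length == 5
        assert aln.rows["dmel"] == "MKV-A"
        assert aln.gene_id == "g1"

    def test_species_regex(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">sp|dmel|CG1\nMK\n>sp|dsim|CG1\nMR\n")
        aln = read_fasta_alignment(p, species_pattern=r"sp\|(\w+)\|")
        assert aln.species == {"dmel", "dsim"}

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta_alignment(p)

    def test_unequal_rows_is_alignment_error(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nMKVLAMKVLA\n>b\nMKVLAMKVL\n")
        with pytest.raises(AlignmentError):
            read_fasta_alignment(p)

    def test_duplicate_species(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nMK\n>a\nMR\n")
        with pytest.raises(DuplicateRecordError):
            read_fasta_alignment(p)


class TestGeneLists:
    def test_read_with_comments(self, tmp_path):
        p = tmp_path / "net.txt"
        p.write_text("# the known network\nCG1652\nCG1656 # lectin\n\nSP\n")
        gs = read_gene_set(p)
        assert gs.members == ("CG1652", "CG1656", "SP")
        assert gs.name == "net"

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            GeneSet("x", ("a", "a"))


class TestBranchTable:
    def test_round_trip(self, tmp_path, tree12, rng):
        vecs = [
            make_vector(
                tree12,
                rng.exponential(0.1, size=21),
                gene_id=f"g{i}",
            )
            for i in range(3)
        ]
        vecs.append(
            make_vector(
                tree12,
                rng.exponential(0.1, size=7),
                gene_id="g_small",
                species=sorted(tree12.leaf_names)[:5],
            )
        )
        p = tmp_path / "rates.tsv"
        write_branch_table(vecs, p)
        back, rejected = read_branch_table(p, tree12)
        assert not rejected
        assert len(back) == 4
        for a, b in zip(vecs, back):
            assert a.gene_id == b.gene_id
            assert a.species_set == b.species_set
            assert a.branch_ids == b.branch_ids
            assert np.array_equal(a.lengths, b.lengths)

    def test_single_gene_21_rows(self, tmp_path, tree12, rng):
        vec = make_vector(tree12, rng.exponential(0.1, 21), gene_id="g0")
        p = tmp_path / "one.tsv"
        write_branch_table([vec], p)
        assert len(p.read_text().splitlines()) == 22  # header + 21 rows
        back, _ = read_branch_table(p, tree12)
        assert len(back) == 1 and len(back[0].lengths) == 21

    def test_negative_length_raises(self, tmp_path, tree12):
        vec = make_vector(tree12, np.full(21, 0.25), gene_id="g0")
        p = tmp_path / "neg.tsv"
        write_branch_table([vec], p)
        text = p.read_text().replace("\t0.25\n", "\t-0.25\n", 1)
        p.write_text(text)
        with pytest.raises(ValueError, match="negative"):
            read_branch_table(p, tree12)

    def test_empty_table(self, tmp_path, tree12):
        p = tmp_path / "empty.tsv"
        p.write_text("gene_id\tbranch_id\tlength\n")
        vecs, rejected = read_branch_table(p, tree12)
        assert vecs == [] and rejected == {}

    def test_unresolvable_branch_is_rejected_with_report(
        self, tmp_path, tree12, rng
    ):
        vec = make_vector(tree12, rng.exponential(0.1, 21), gene_id="g0")
        p = tmp_path / "bad.tsv"
        write_branch_table([vec], p)
        lines = p.read_text().splitlines()
        parts = lines[1].split("\t")
        parts[1] = "dmel,notaspecies|" + parts[1].split("|")[1]
        lines[1] = "\t".join(parts)
        p.write_text("\n".join(lines) + "\n")
        vecs, rejected = read_branch_table(p, tree12)
        assert vecs == []
        assert "g0" in rejected

    def test_branch_id_encoding_round_trip(self, tree12):
        S = tree12.leaf_names
        for b in tree12.branch_ids:
            a, c = decode_branch_id(encode_branch_id(b, S))
            assert a | c == S
            assert b in (a, c)
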