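"""Readers and writers for the formats the pipeline touches.

FASTA amino-acid alignments (one ortholog group per file), Newick species
topologies, TSV branch-length tables (the generic ingestion path for
externally estimated branch lengths, e.g. parsed PAML output), and plain
gene lists.  Branch-table rows identify branches by both sides of their
leaf bipartition (``sideA|sideB``, species comma-joined within a side) so a
gene's species set and branch identities are recoverable from the table
alone, given the master topology.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .tree import BranchId, Phylogeny, TreeError

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_ALLOWED_CHARS = frozenset(AA20 + "X-")

__all__ = [
    "AA20",
    "OrthologAlignment",
    "GeneSet",
    "FormatError",
    "AlignmentError",
    "DuplicateRecordError",
    "BranchTableError",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_newick",
    "write_newick",
    "read_gene_set",
    "write_gene_set",
    "read_branch_table",
    "write_branch_table",
    "encode_branch_id",
    "decode_branch_id",
]


class FormatError(ValueError):
    """File is not in the expected format (e.g. empty FASTA)."""


class AlignmentError(ValueError):
    """Rows of unequal length or disallowed characters."""


class DuplicateRecordError(ValueError):
    """Two records resolve to the same species."""


class BranchTableError(ValueError):
    """Branch table malformed or unresolvable against the topology."""


@dataclass(eq=False)
class OrthologAlignment:
    """Aligned amino-acid sequences for one ortholog group, keyed by species.

    Rows must be equal length over the alphabet of 20 amino acids, gap
    ``-`` and ambiguity ``X``.  Gap handling is deferred to distance
    computation (pairwise deletion), not ingestion.
    """

    gene_id: str
    rows: Dict[str, str]

    def __post_init__(self):
        if not self.rows:
            raise AlignmentError(f"{self.gene_id}: alignment has no rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.gene_id}: rows of unequal length {sorted(lengths)}"
            )
        self.rows = {sp: seq.upper() for sp, seq in self.rows.items()}
        for sp, seq in self.rows.items():
            bad = set(seq) - _ALLOWED_CHARS
            if bad:
                raise AlignmentError(
                    f"{self.gene_id}/{sp}: disallowed characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def species(self) -> frozenset:
        return frozenset(self.rows)

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene ids (query set, candidate pool, background...)."""

    name: str
    members: Tuple[str, ...]

    def __post_init__(self):
        members = tuple(self.members)
        object.__setattr__(self, "members", members)
        if not members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(members)) != len(members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, gene_id) -> bool:
        return gene_id in set(self.members)


def read_fasta_alignment(
    path,
    gene_id: Optional[str] = None,
    species_pattern: Optional[str] = None,
) -> OrthologAlignment:
    """Read one FASTA alignment; record ids are mapped to species names.

    By default the species name is the first whitespace-delimited token of
    the record header (the convention of species-prefixed ortholog files);
    ``species_pattern`` supplies a regex for other dialects (first group if
    the pattern has groups, else the whole match, searched in the full
    description line).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    rows: Dict[str, str] = {}
    for rec in records:
        if species_pattern is None:
            name = rec.id
        else:
            m = re.search(species_pattern, rec.description)
            if m is None:
                raise FormatError(
                    f"{path}: header {rec.description!r} does not match "
                    f"species pattern {species_pattern!r}"
                )
            name = m.group(1) if m.lastindex else m.group(0)
        if name in rows:
            raise DuplicateRecordError(f"{path}: duplicate species {name!r}")
        rows[name] = str(rec.seq)
    return OrthologAlignment(gene_id or path.stem, rows)


def write_fasta_alignment(aln: OrthologAlignment, path) -> None:
    with open(path, "w") as fh:
        for sp in sorted(aln.rows):
            fh.write(f">{sp}\n{aln.rows[sp]}\n")


def read_newick(path) -> Phylogeny:
    """Read a Newick topology; see :meth:`Phylogeny.from_newick`."""
    text = Path(path).read_text()
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_gene_set(path, name: Optional[str] = None) -> GeneSet:
    """Plain-text gene list: one id per line, ``#`` starts a comment."""
    members = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            members.append(line)
    if not members:
        raise FormatError(f"{path}: no gene ids")
    return GeneSet(name or Path(path).stem, tuple(members))


def write_gene_set(genes: GeneSet, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes.members))


# -- branch tables -------------------------------------------------------


def encode_branch_id(branch: BranchId, species_set: Iterable[str]) -> str:
    """Serialize a branch as both sides of its bipartition.

    Sides are comma-joined sorted species, smaller side first (ties broken
    lexicographically), joined by ``|``.
    """
    species_set = frozenset(species_set)
    a = tuple(sorted(branch))
    b = tuple(sorted(species_set - frozenset(branch)))
    if (len(b), b) < (len(a), a):
        a, b = b, a
    return ",".join(a) + "|" + ",".join(b)


def decode_branch_id(token: str) -> Tuple[frozenset, frozenset]:
    parts = token.split("|")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise BranchTableError(f"malformed branch id {token!r}")
    a = frozenset(parts[0].split(","))
    b = frozenset(parts[1].split(","))
    if a & b:
        raise BranchTableError(f"overlapping bipartition sides in {token!r}")
    return a, b


def write_branch_table(vectors, path) -> None:
    """Emit gene_id / branch_id / length TSV, round-trippable through
    :func:`read_branch_table`."""
    with open(path, "w") as fh:
        fh.write("gene_id\tbranch_id\tlength\n")
        for v in vectors:
            for bid, l in zip(v.branch_ids, v.lengths):
                fh.write(
                    f"{v.gene_id}\t{encode_branch_id(bid, v.species_set)}"
                    f"\t{l:.17g}\n"
                )


def read_branch_table(path, tree: Phylogeny):
    """Read per-gene branch lengths, resolving branch ids against ``tree``
    (or its prunings).

    Returns ``(vectors, rejected)`` where ``rejected`` maps gene ids whose
    branches could not be resolved to a reason string.  Negative lengths
    raise immediately; an empty table yields no vectors.
    """
    from .branch_rates import BranchRateVector

    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"gene_id": str, "branch_id": str},
        float_precision="round_trip",
    )
    required = {"gene_id", "branch_id", "length"}
    if not required <= set(df.columns):
        raise BranchTableError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    if df.empty:
        return [], {}
    if (df["length"].astype(float) < 0).any():
        raise ValueError(f"{path}: negative branch length")

    vectors: List[BranchRateVector] = []
    rejected: Dict[str, str] = {}
    for gene_id, sub in df.groupby("gene_id", sort=False):
        try:
            tokens = [decode_branch_id(t) for t in sub["branch_id"]]
        except BranchTableError as exc:
            rejected[gene_id] = str(exc)
            continue
        species = tokens[0][0] | tokens[0][1]
        if any((a | b) != species for a, b in tokens):
            rejected[gene_id] = "inconsistent species sets across branch ids"
            continue
        if not species <= tree.leaf_names:
            rejected[gene_id] = "species not in topology: " + ",".join(
                sorted(species - tree.leaf_names)
            )
            continue
        try:
            pruned = tree.prune(species)[0] if species != tree.leaf_names else tree
        except TreeError as exc:
            rejected[gene_id] = str(exc)
            continue
        ref = min(species)
        lengths: Dict[frozenset, float] = {}
        ok = True
        for (a, b), l in zip(tokens, sub["length"].astype(float)):
            bid = b if ref in a else a
            if bid in lengths:
                rejected[gene_id] = f"duplicate branch {encode_branch_id(bid, species)}"
                ok = False
                break
            lengths[bid] = l
        if not ok:
            continue
        if set(lengths) != set(pruned.branch_ids):
            rejected[gene_id] = "branch ids do not match the pruned topology"
            continue
        vectors.append(
            BranchRateVector(
                gene_id=gene_id,
                species_set=frozenset(species),
                branch_ids=pruned.branch_ids,
                lengths=np.array([lengths[b] for b in pruned.branch_ids]),
            )
        )
    return vectors, rejected
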