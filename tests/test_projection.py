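"""The projection operation: species-tree signal removal and winsorization."""

import numpy as np
import pytest

from ercov import (
    GeneSet,
    InsufficientUniverseError,
    TooFewSpeciesError,
    build_projection,
    group_by_species_set,
    reproject_with_background,
    restrict_vector,
)
from ercov.simulate import SimulationSpec, simulate_branch_rates
from ercov.tree import PruneCache

from conftest import make_vector


class TestGrouping:
    def test_direct_grouping(self, tree12, rng):
        sp = sorted(tree12.leaf_names)
        vecs = [
            make_vector(tree12, rng.exponential(0.1, 21), "a"),
            make_vector(tree12, rng.exponential(0.1, 21), "b"),
            make_vector(
                tree12, rng.exponential(0.1, 19), "c", species=sp[:11]
            ),
        ]
        groups, excluded = group_by_species_set(vecs)
        assert not excluded
        sizes = sorted(len(v) for v in groups.values())
        assert sizes == [1, 2]

    def test_min_species_exclusion(self, tree12, rng):
        sp = sorted(tree12.leaf_names)
        small = make_vector(
            tree12, rng.exponential(0.1, 5), "tiny", species=sp[:4]
        )
        groups, excluded = group_by_species_set([small])
        assert excluded == ["tiny"]
        assert groups == {}

    def test_matches_brute_force_grouping(self, tree12, rng):
        sp = sorted(tree12.leaf_names)
        vecs = []
        for i in range(1000):
            k = int(rng.integers(4, 13))
            keep = sorted(rng.choice(sp, size=k, replace=False))
            n_br = 2 * k - 3
            vecs.append(
                make_vector(
                    tree12, rng.exponential(0.1, n_br), f"g{i}", species=keep
                )
            )
        groups, excluded = group_by_species_set(vecs, min_species=5)
        # brute-force oracle
        oracle = {}
        oracle_excluded = []
        for v in vecs:
            if len(v.species_set) < 5:
                oracle_excluded.append(v.gene_id)
            else:
                oracle.setdefault(v.species_set, []).append(v.gene_id)
        assert excluded == oracle_excluded
        assert {k: [v.gene_id for v in vs] for k, vs in groups.items()} == oracle


class TestProjection:
    def _universe(self, tree, n=40, seed=0):
        spec = SimulationSpec(n_genes=n, tree=tree, seed=seed)
        return simulate_branch_rates(spec)[0]

    def test_residuals_orthogonal_to_expected(self, tree12):
        """The orthogonal-projection variant annihilates the mean
        direction exactly (pre-winsorization)."""
        uni = self._universe(tree12)
        table = build_projection(
            tree12.leaf_names, uni, tree=tree12, method="projection"
        )
        m = table.expected
        for g in table.members:
            assert abs(table.residuals_raw[g] @ m) < 1e-10

    def test_gene_equal_to_mean_direction_has_zero_residual(self, tree12):
        uni = self._universe(tree12, n=30)
        table = build_projection(
            tree12.leaf_names, uni, tree=tree12, method="projection"
        )
        aligned = make_vector(tree12, 3.7 * table.expected, "aligned")
        table2 = build_projection(
            tree12.leaf_names, list(uni) + [aligned], tree=tree12,
            method="projection",
        )
        # residual of the gene lying along the (new) mean is ~0 relative to
        # the residual scale of ordinary genes
        scale = np.median(
            [np.linalg.norm(table2.residuals_raw[g]) for g in table2.members]
        )
        # the added gene shifts m slightly; project it against the new m
        u = 3.7 * table.expected
        u = u / np.linalg.norm(u)
        m2 = table2.expected
        r = u - (u @ m2) / (m2 @ m2) * m2
        assert np.allclose(table2.residuals_raw["aligned"], r)
        assert np.linalg.norm(r) < 0.2 * scale

    def test_scale_invariance(self, tree12, rng):
        uni = self._universe(tree12)
        target = tree12.leaf_names
        t1 = build_projection(target, uni, tree=tree12)
        g = uni[7]
        scaled = make_vector(tree12, 100.0 * g.lengths, g.gene_id)
        uni2 = [scaled if v.gene_id == g.gene_id else v for v in uni]
        t2 = build_projection(target, uni2, tree=tree12)
        assert np.allclose(
            t1.residuals[g.gene_id], t2.residuals[g.gene_id], atol=1e-12
        )

    def test_two_toy_genes_orthogonality(self, tree12):
        sp = sorted(tree12.leaf_names)[:5]
        sub = tree12.prune(sp)[0]
        a = make_vector(tree12, np.arange(1.0, 8.0), "a", species=sp)
        b = make_vector(tree12, np.ones(7), "b", species=sp)
        table = build_projection(sp, [a, b], tree=tree12, method="projection")
        m = table.expected
        for g in ("a", "b"):
            assert abs(table.residuals_raw[g] @ m) < 1e-10

    def test_winsorization_clamps_at_exact_boundary(self, tree12, rng):
        uni = self._universe(tree12, n=50)
        # plant a wild outlier on one branch of one gene
        v = uni[0]
        lengths = v.lengths.copy()
        lengths[3] *= 60.0
        uni[0] = make_vector(tree12, lengths, v.gene_id)
        table = build_projection(
            tree12.leaf_names, uni, tree=tree12, winsor_bound=2.0
        )
        R_raw = np.array([table.residuals_raw[g] for g in table.members])
        R = np.array([table.residuals[g] for g in table.members])
        mu = R_raw.mean(axis=0)
        sd = R_raw.std(axis=0, ddof=1)
        assert table.n_clamped > 0
        # every clamped entry sits exactly on mean +/- 2 SD of its column
        moved = R != R_raw
        for i, k in zip(*np.nonzero(moved)):
            assert R[i, k] == pytest.approx(
                mu[k] + np.sign(R_raw[i, k] - mu[k]) * 2.0 * sd[k]
            )
        # and no entry lies beyond the bound
        assert (R <= mu + 2 * sd + 1e-12).all()
        assert (R >= mu - 2 * sd - 1e-12).all()

    def test_superset_genes_contribute(self, tree12, rng):
        sp = sorted(tree12.leaf_names)
        full = self._universe(tree12, n=10)
        target = sp[:6]
        table = build_projection(target, full, tree=tree12)
        assert len(table.members) == 10
        assert table.n_branches == 2 * 6 - 3

    def test_insufficient_universe(self, tree12):
        uni = self._universe(tree12, n=1)
        with pytest.raises(InsufficientUniverseError):
            build_projection(tree12.leaf_names, uni, tree=tree12)

    def test_target_below_min_species(self, tree12):
        uni = self._universe(tree12)
        with pytest.raises(TooFewSpeciesError):
            build_projection(
                sorted(tree12.leaf_names)[:4], uni, tree=tree12
            )

    def test_tree_signal_removal(self, tree12):
        """Raw branch vectors correlate strongly (shared tree); residuals
        do not (|mean pairwise r| small)."""
        spec = SimulationSpec(
            n_genes=300, tree=tree12, branch_noise_sd=0.5, seed=42
        )
        uni = simulate_branch_rates(spec)[0]
        raw = np.array([v.lengths for v in uni])

        def mean_pairwise_r(M):
            Z = M - M.mean(axis=1, keepdims=True)
            Z /= np.linalg.norm(Z, axis=1, keepdims=True)
            n = len(Z)
            total = np.linalg.norm(Z.sum(axis=0)) ** 2 - n
            return total / (n * (n - 1))

        assert mean_pairwise_r(raw) > 0.2
        table = build_projection(tree12.leaf_names, uni, tree=tree12)
        R = table.residual_matrix(table.members)
        assert -0.05 < mean_pairwise_r(R) < 0.05


class TestRestrictedBackground:
    def test_full_background_identical(self, tree12):
        spec = SimulationSpec(n_genes=20, tree=tree12, seed=3)
        uni = simulate_branch_rates(spec)[0]
        all_ids = GeneSet("all", tuple(v.gene_id for v in uni))
        t1 = build_projection(tree12.leaf_names, uni, tree=tree12)
        t2 = reproject_with_background(
            tree12.leaf_names, all_ids, uni, tree=tree12
        )
        for g in t1.members:
            assert np.allclose(t1.residuals[g], t2.residuals[g])

    def test_two_gene_background_mean(self, tree12):
        spec = SimulationSpec(n_genes=10, tree=tree12, seed=4)
        uni = simulate_branch_rates(spec)[0]
        bg = GeneSet("bg", (uni[0].gene_id, uni[1].gene_id))
        table = reproject_with_background(
            tree12.leaf_names, bg, uni, tree=tree12
        )
        u0 = uni[0].lengths / np.linalg.norm(uni[0].lengths)
        u1 = uni[1].lengths / np.linalg.norm(uni[1].lengths)
        assert np.allclose(table.expected, (u0 + u1) / 2)

    def test_disjoint_background_errors(self, tree12):
        spec = SimulationSpec(n_genes=10, tree=tree12, seed=5)
        uni = simulate_branch_rates(spec)[0]
        bg = GeneSet("bg", ("nope1", "nope2"))
        with pytest.raises(InsufficientUniverseError):
            reproject_with_background(
                tree12.leaf_names, bg, uni, tree=tree12
            )


class TestRestrictVector:
    def test_restriction_sums_suppressed_paths(self, tree12, rng):
        cache = PruneCache(tree12)
        v = make_vector(tree12, rng.exponential(0.1, 21), "g")
        target = frozenset(sorted(tree12.leaf_names)[:5])
        r = restrict_vector(v, cache, target)
        assert r.species_set == target
        assert len(r.lengths) == 7
        # total length over retained paths is conserved or reduced
        assert r.lengths.sum() <= v.lengths.sum() + 1e-12
        # distances between retained leaves are preserved
        full = tree12.with_lengths(dict(zip(v.branch_ids, v.lengths)))
        sub = cache.pruned(target).with_lengths(
            dict(zip(r.branch_ids, r.lengths))
        )
        sp_f, d_f = full.leaf_distances()
        sp_s, d_s = sub.leaf_distances()
        idx = [sp_f.index(s) for s in sp_s]
        assert np.allclose(d_s, d_f[np.ix_(idx, idx)])
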