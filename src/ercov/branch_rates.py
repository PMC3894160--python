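"""Per-gene branch-length estimation from amino-acid alignments.

The estimator is deliberately simple and self-contained: Poisson-corrected
pairwise amino-acid distances (pairwise deletion of gaps and ``X``) fitted
to the pruned species topology by nonnegative ordinary least squares on
path lengths.  On additive (noise-free) distance matrices the fit recovers
the generating branch lengths exactly.  Users who prefer maximum-likelihood
branch lengths under an empirical substitution matrix can estimate them
externally and ingest the TSV tables via :func:`ercov.io.read_branch_table`;
downstream modules are agnostic to the provenance of the vectors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy.optimize import nnls

from .io import OrthologAlignment
from .tree import Phylogeny, TooFewSpeciesError, TreeError

__all__ = [
    "BranchRateVector",
    "DistanceMatrix",
    "SaturationError",
    "UndefinedDistanceError",
    "pairwise_distances",
    "fit_branch_lengths",
    "branch_rates_from_alignment",
    "estimate_branch_rates",
]


class SaturationError(ValueError):
    """A pairwise distance is saturated (all shared columns differ)."""


class UndefinedDistanceError(ValueError):
    """A pair shares no ungapped columns; no distance can be formed."""


@dataclass(eq=False)
class BranchRateVector:
    """Raw branch lengths for one gene on the pruned topology of its
    species set; ``branch_ids`` are leaf bipartitions in canonical order."""

    gene_id: str
    species_set: frozenset
    branch_ids: tuple
    lengths: np.ndarray

    def __post_init__(self):
        self.species_set = frozenset(self.species_set)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if len(self.species_set) < 3:
            raise ValueError(
                f"{self.gene_id}: species set smaller than 3"
            )
        if len(self.branch_ids) != len(self.lengths):
            raise ValueError(f"{self.gene_id}: branch/length size mismatch")
        if (self.lengths < 0).any():
            raise ValueError(f"{self.gene_id}: negative branch length")

    @property
    def n_species(self) -> int:
        return len(self.species_set)

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())


@dataclass(eq=False)
class DistanceMatrix:
    """Pairwise amino-acid distances (substitutions/site).

    ``d`` is symmetric with zero diagonal; entries are NaN where no shared
    ungapped columns exist and +inf where the pair is saturated (flagged in
    ``saturated``).  ``usable_sites`` counts shared ungapped columns.
    """

    gene_id: str
    species: tuple
    d: np.ndarray
    usable_sites: np.ndarray
    saturated: np.ndarray

    @property
    def has_undefined(self) -> bool:
        off = ~np.eye(len(self.species), dtype=bool)
        return bool(np.isnan(self.d[off]).any())

    @property
    def has_saturated(self) -> bool:
        return bool(self.saturated.any())


def pairwise_distances(
    aln: OrthologAlignment,
    cap_saturation: bool = False,
    saturation_cap: float = 0.95,
) -> DistanceMatrix:
    """Poisson-corrected p-distances with pairwise deletion.

    For each pair, ``p`` = mismatches / shared ungapped columns (gap and
    ``X`` columns removed per pair), and ``d = -ln(1 - p)``.  Saturated
    pairs (``p = 1``) are flagged; with ``cap_saturation`` the proportion
    is clamped at ``saturation_cap`` before correction instead, so no pair
    is flagged.  Pairs with zero shared columns get NaN.
    """
    if aln.n_rows < 2:
        raise ValueError(f"{aln.gene_id}: need at least 2 rows")
    species = tuple(sorted(aln.rows))
    M = np.array([list(aln.rows[sp]) for sp in species])
    valid = (M != "-") & (M != "X")
    n = len(species)
    d = np.zeros((n, n))
    usable = np.zeros((n, n), dtype=int)
    saturated = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        shared = valid[i] & valid[j]
        m = int(shared.sum())
        usable[i, j] = usable[j, i] = m
        if m == 0:
            d[i, j] = d[j, i] = np.nan
            continue
        p = float((M[i][shared] != M[j][shared]).sum()) / m
        if cap_saturation:
            p = min(p, saturation_cap)
        if p >= 1.0:
            d[i, j] = d[j, i] = np.inf
            saturated[i, j] = saturated[j, i] = True
        else:
            d[i, j] = d[j, i] = -np.log1p(-p)
    return DistanceMatrix(aln.gene_id, species, d, usable, saturated)


def fit_branch_lengths(
    dm: DistanceMatrix, tree: Phylogeny
) -> Tuple[BranchRateVector, np.ndarray]:
    """Least-squares branch lengths on ``tree`` from pairwise distances.

    Minimizes the unweighted sum of squared differences between tree path
    lengths and the observed distances, subject to nonnegativity (NNLS).
    Returns the fitted vector and the induced path-length matrix for
    diagnostics.  Refuses saturated or undefined distances: such genes are
    excluded upstream rather than fitted to fabricated values.
    """
    if frozenset(dm.species) != tree.leaf_names:
        raise TreeError(
            f"{dm.gene_id}: distance matrix species do not match the tree"
        )
    if dm.has_saturated:
        raise SaturationError(f"{dm.gene_id}: saturated distances present")
    if dm.has_undefined:
        raise UndefinedDistanceError(
            f"{dm.gene_id}: pair(s) with no shared ungapped columns"
        )
    species = dm.species
    pairs = list(itertools.combinations(range(len(species)), 2))
    pos = {b: k for k, b in enumerate(tree.branch_ids)}
    A = np.zeros((len(pairs), len(tree.branch_ids)))
    y = np.empty(len(pairs))
    for row, (i, j) in enumerate(pairs):
        for b in tree.path_branches(species[i], species[j]):
            A[row, pos[b]] = 1.0
        y[row] = dm.d[i, j]
    x, _rnorm = nnls(A, y)
    fitted_paths = A @ x
    fitted = np.zeros_like(dm.d)
    for row, (i, j) in enumerate(pairs):
        fitted[i, j] = fitted[j, i] = fitted_paths[row]
    vec = BranchRateVector(
        gene_id=dm.gene_id,
        species_set=tree.leaf_names,
        branch_ids=tree.branch_ids,
        lengths=x,
    )
    return vec, fitted


def branch_rates_from_alignment(
    aln: OrthologAlignment,
    tree: Phylogeny,
    min_species: int = 3,
    cap_saturation: bool = False,
) -> BranchRateVector:
    """Distance + NNLS pipeline for one alignment; the tree is pruned to
    the alignment's species first."""
    species = aln.species
    if not species <= tree.leaf_names:
        raise TreeError(
            f"{aln.gene_id}: species not in topology: "
            + ",".join(sorted(species - tree.leaf_names))
        )
    if len(species) < max(min_species, 3):
        raise TooFewSpeciesError(
            f"{aln.gene_id}: only {len(species)} species"
        )
    sub = tree if species == tree.leaf_names else tree.prune(species)[0]
    dm = pairwise_distances(aln, cap_saturation=cap_saturation)
    vec, _ = fit_branch_lengths(dm, sub)
    return vec


def estimate_branch_rates(
    alignments: Iterable[OrthologAlignment],
    tree: Phylogeny,
    min_species: int = 5,
    cap_saturation: bool = False,
):
    """Batch estimation; genes that cannot be fitted are reported, not
    silently dropped.  Returns ``(vectors, failures)`` with ``failures``
    mapping gene id to the reason string."""
    vectors: List[BranchRateVector] = []
    failures: Dict[str, str] = {}
    for aln in alignments:
        try:
            vectors.append(
                branch_rates_from_alignment(
                    aln, tree, min_species=min_species,
                    cap_saturation=cap_saturation,
                )
            )
        except (ValueError, TreeError) as exc:
            failures[aln.gene_id] = str(exc)
    return vectors, failures
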