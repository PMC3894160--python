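"""Relative-rate transformation: removing the species-tree signal.

Raw branch lengths of different genes are strongly correlated simply
because long branches of the species tree are long for every gene.  For a
target species set, every background ("universe") gene covering at least
those species is pruned down, scaled to unit Euclidean norm (so gene-wide
rate differences drop out), and transformed against the expected tree
``m`` (the per-branch mean of the normalized vectors).

Two residual formulas are provided:

``method="ratio"`` (default) -- rates relative to the expected branch
length, centred per gene:

    u_g = b_g / ||b_g||,   m = mean_g u_g,
    r_gk = u_gk / m_k - mean_k(u_gk / m_k).

Dividing by the expected length puts every branch on a comparable scale,
so a correlation across branches weighs short and long branches equally;
a gene evolving exactly proportionally to the expected tree has a zero
residual.

``method="projection"`` -- removal of the component along the mean
direction:

    r_g = u_g - ((u_g . m) / (m . m)) m,

which leaves every raw residual exactly orthogonal to ``m`` but keeps
branch columns heteroscedastic (residual variance tracks branch length),
noticeably widening pairwise-correlation nulls.

Both variants are scale-invariant (the unit-norm step comes first).  To
limit outlier influence each branch column of the residual table is then
clamped (winsorized) at its mean +/- 2 SD by default.  One table is built
per unique species set, because pairs of genes are compared on the
intersection of their coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .branch_rates import BranchRateVector
from .io import GeneSet
from .tree import Phylogeny, PruneCache, TooFewSpeciesError

__all__ = [
    "ProjectionTable",
    "InsufficientUniverseError",
    "group_by_species_set",
    "restrict_vector",
    "build_projection",
    "reproject_with_background",
]

MIN_SPECIES_DEFAULT = 5
WINSOR_BOUND_DEFAULT = 2.0


class InsufficientUniverseError(ValueError):
    """Fewer than two universe genes cover the target species set."""


def group_by_species_set(
    vectors: Iterable[BranchRateVector], min_species: int = MIN_SPECIES_DEFAULT
):
    """Partition genes by their exact species set.

    Genes with coverage below ``min_species`` are excluded and reported.
    Returns ``(groups, excluded)`` with ``groups`` mapping each frozenset
    of species to the list of genes having exactly that coverage.
    """
    groups: Dict[frozenset, List[BranchRateVector]] = {}
    excluded: List[str] = []
    for v in vectors:
        if v.n_species < min_species:
            excluded.append(v.gene_id)
            continue
        groups.setdefault(v.species_set, []).append(v)
    return groups, excluded


def restrict_vector(
    vec: BranchRateVector, cache: PruneCache, target: Iterable[str]
) -> BranchRateVector:
    """Prune a gene's branch-rate vector to a subset of its species,
    summing lengths along suppressed paths."""
    target = frozenset(target)
    if not target <= vec.species_set:
        raise ValueError(
            f"{vec.gene_id}: target species not covered by this gene"
        )
    if target == vec.species_set:
        return vec
    branch_ids, idx = cache.restriction(vec.species_set, target)
    lengths = np.array([vec.lengths[ix].sum() for ix in idx])
    return BranchRateVector(
        gene_id=vec.gene_id,
        species_set=target,
        branch_ids=branch_ids,
        lengths=lengths,
    )


@dataclass(eq=False)
class ProjectionTable:
    """Residual relative rates for one species set.

    ``expected`` is the per-branch mean of the normalized universe vectors
    (the expected tree ``m``); ``residuals`` holds each member gene's
    winsorized residual vector and ``residuals_raw`` the pre-clamp values
    (orthogonal to ``m``).  Branches whose expected length is not strictly
    positive are dropped table-wide and listed in ``dropped_branches``.
    """

    species_set: frozenset
    branch_ids: tuple
    expected: np.ndarray
    residuals: Dict[str, np.ndarray]
    residuals_raw: Dict[str, np.ndarray]
    background: str
    winsor_bound: float
    method: str
    dropped_branches: tuple = ()
    dropped_genes: tuple = ()
    n_clamped: int = 0

    @property
    def members(self) -> Tuple[str, ...]:
        return tuple(self.residuals)

    @property
    def n_branches(self) -> int:
        return len(self.branch_ids)

    def residual_matrix(self, order: Optional[Sequence[str]] = None) -> np.ndarray:
        order = list(order) if order is not None else list(self.residuals)
        return np.array([self.residuals[g] for g in order])


def _winsorize_columns(R: np.ndarray, bound: float):
    mu = R.mean(axis=0)
    sd = R.std(axis=0, ddof=1) if R.shape[0] > 1 else np.zeros(R.shape[1])
    lo = mu - bound * sd
    hi = mu + bound * sd
    clamped = np.clip(R, lo, hi)
    return clamped, int((clamped != R).sum())


def build_projection(
    target_set: Iterable[str],
    universe: Sequence[BranchRateVector],
    tree: Optional[Phylogeny] = None,
    cache: Optional[PruneCache] = None,
    winsor_bound: float = WINSOR_BOUND_DEFAULT,
    min_species: int = MIN_SPECIES_DEFAULT,
    background: Optional[Iterable[str]] = None,
    background_name: str = "all",
    method: str = "ratio",
) -> ProjectionTable:
    """Build the residual-rate table for one species set.

    Every universe gene whose coverage is a superset of ``target_set``
    contributes (pruned down to it); the expected tree is their mean
    normalized vector, or the mean over ``background`` gene ids only when a
    restricted background universe is requested.  Residuals are computed
    for all contributing genes either way.
    """
    target = frozenset(target_set)
    if len(target) < min_species:
        raise TooFewSpeciesError(
            f"target set of {len(target)} species is below the "
            f"minimum of {min_species}"
        )
    if cache is None:
        if tree is None:
            raise ValueError("either tree or cache must be given")
        cache = PruneCache(tree)
    if method not in ("projection", "ratio"):
        raise ValueError(f"unknown method {method!r}")

    contributors = [v for v in universe if target <= v.species_set]
    ids = [v.gene_id for v in contributors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in universe")
    if len(contributors) < 2:
        raise InsufficientUniverseError(
            f"only {len(contributors)} universe gene(s) cover the target set"
        )

    branch_ids = cache.pruned(target).branch_ids
    B = np.array(
        [restrict_vector(v, cache, target).lengths for v in contributors]
    )
    norms = np.linalg.norm(B, axis=1)
    keep = norms > 0
    dropped_genes = tuple(g for g, k in zip(ids, keep) if not k)
    if dropped_genes:
        warnings.warn(
            f"dropping zero-norm gene(s): {', '.join(dropped_genes)}",
            stacklevel=2,
        )
        B, norms = B[keep], norms[keep]
        ids = [g for g, k in zip(ids, keep) if k]
    if len(ids) < 2:
        raise InsufficientUniverseError(
            "fewer than 2 usable universe genes after dropping zero-norm vectors"
        )
    U = B / norms[:, None]

    if background is not None:
        bg = frozenset(background)
        mask = np.array([g in bg for g in ids])
        if mask.sum() < 2:
            raise InsufficientUniverseError(
                f"only {int(mask.sum())} background gene(s) cover the target set"
            )
        m = U[mask].mean(axis=0)
    else:
        m = U.mean(axis=0)

    keep_cols = m > 0
    dropped_branches = tuple(
        b for b, k in zip(branch_ids, keep_cols) if not k
    )
    if dropped_branches:
        branch_ids = tuple(b for b, k in zip(branch_ids, keep_cols) if k)
        U = U[:, keep_cols]
        m = m[keep_cols]

    if method == "projection":
        coef = (U @ m) / (m @ m)
        R_raw = U - coef[:, None] * m[None, :]
    else:  # ratio variant: per-branch relative rate, centred per gene
        R_raw = U / m[None, :]
        R_raw = R_raw - R_raw.mean(axis=1, keepdims=True)

    R, n_clamped = _winsorize_columns(R_raw, winsor_bound)
    return ProjectionTable(
        species_set=target,
        branch_ids=branch_ids,
        expected=m,
        residuals={g: R[i] for i, g in enumerate(ids)},
        residuals_raw={g: R_raw[i] for i, g in enumerate(ids)},
        background=background_name,
        winsor_bound=winsor_bound,
        method=method,
        dropped_branches=dropped_branches,
        dropped_genes=dropped_genes,
        n_clamped=n_clamped,
    )


def reproject_with_background(
    target_set: Iterable[str],
    restricted_universe: GeneSet,
    all_vectors: Sequence[BranchRateVector],
    **kwargs,
) -> ProjectionTable:
    """Projection with the expected tree estimated from a restricted
    background universe (e.g. reproductive proteins only), while residuals
    are still computed for every contributing gene."""
    return build_projection(
        target_set,
        all_vectors,
        background=set(restricted_universe.members),
        background_name=restricted_universe.name,
        **kwargs,
    )
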