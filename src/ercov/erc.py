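"""Pairwise evolutionary rate covariation and empirical p-values.

The ERC value of a gene pair is the Pearson correlation of their residual
rate vectors over the branches of their *shared* species set.  Because the
distribution of correlations depends on the species set (fewer species =
fewer branches = wider nulls), each observed value is converted to an
empirical p-value against the observed distribution of ERC values for the
same species set, sampled from gene pairs of the background universe.
p-values are one-sided by default (only elevated ERC is interpreted) with
an add-one correction so they are never zero; ties count toward the tail.
"""

from __future__ import annotations

import hashlib
import itertools
from collections import OrderedDict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .branch_rates import BranchRateVector
from .io import GeneSet
from .projection import (
    MIN_SPECIES_DEFAULT,
    WINSOR_BOUND_DEFAULT,
    ProjectionTable,
    build_projection,
)
from .tree import Phylogeny, PruneCache

__all__ = [
    "ERCResult",
    "NullDistribution",
    "UndefinedCorrelationError",
    "PairSkipped",
    "erc_value",
    "empirical_pvalue",
    "build_null",
    "ERCAnalysis",
    "erc_matrix",
    "write_erc_table",
]

NULL_PAIRS_DEFAULT = 10_000
LOW_POWER_NULL = 100


class UndefinedCorrelationError(ValueError):
    """A residual vector is constant; the correlation is undefined."""


class PairSkipped(Exception):
    """A gene pair could not be scored (reason recorded, pair counted)."""

    def __init__(self, gene_a: str, gene_b: str, reason: str):
        super().__init__(f"{gene_a}-{gene_b}: {reason}")
        self.gene_a = gene_a
        self.gene_b = gene_b
        self.reason = reason


@dataclass(eq=False)
class ERCResult:
    """One scored pair: correlation, species context and empirical p."""

    gene_a: str
    gene_b: str
    shared_set: frozenset
    n_branches: int
    r: float
    p_emp: float

    @property
    def n_species(self) -> int:
        return len(self.shared_set)


@dataclass(eq=False)
class NullDistribution:
    """ERC values of sampled background gene pairs for one species set."""

    species_set: frozenset
    values: np.ndarray
    pair_a: tuple
    pair_b: tuple

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def low_power(self) -> bool:
        return self.n < LOW_POWER_NULL


def erc_value(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two residual-rate vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 branches")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def empirical_pvalue(
    r_obs: float,
    null: Union[NullDistribution, np.ndarray, Sequence[float]],
    alternative: str = "greater",
) -> float:
    """Rank-based tail probability of ``r_obs`` within the null.

    ``p = (1 + #{null >= r_obs}) / (1 + n)`` (add-one, so p > 0; ties count
    toward the tail).  ``alternative="two-sided"`` compares magnitudes.
    """
    values = null.values if isinstance(null, NullDistribution) else np.asarray(
        null, dtype=float
    )
    n = len(values)
    if n == 0:
        raise ValueError("empty null distribution")
    if alternative == "greater":
        c = int((values >= r_obs).sum())
    elif alternative == "two-sided":
        c = int((np.abs(values) >= abs(r_obs)).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + c) / (1 + n)


def _standardized_rows(R: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Rows scaled so the dot product of two rows is their Pearson r;
    returns the matrix and a mask of usable (non-constant) rows."""
    mu = R.mean(axis=1, keepdims=True)
    C = R - mu
    ss = np.sqrt((C**2).sum(axis=1, keepdims=True))
    usable = ss[:, 0] > 0
    ss[ss == 0] = 1.0
    return C / ss, usable


def build_null(
    projection: ProjectionTable,
    n_pairs: int = NULL_PAIRS_DEFAULT,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> NullDistribution:
    """Sample the observed ERC distribution for one species set.

    Up to ``n_pairs`` unordered member pairs are drawn uniformly without
    replacement (all pairs when fewer exist); deterministic under seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    members = list(projection.residuals)
    if len(members) < 2:
        raise ValueError("projection has fewer than 2 members")
    R = projection.residual_matrix(members)
    Z, usable = _standardized_rows(R)
    members = [g for g, u in zip(members, usable) if u]
    Z = Z[usable]
    m = len(members)
    if m < 2:
        raise ValueError("fewer than 2 non-constant members")
    ii, jj = np.triu_indices(m, k=1)
    total = len(ii)
    if total > n_pairs:
        take = rng.choice(total, size=n_pairs, replace=False)
        take.sort()
        ii, jj = ii[take], jj[take]
    values = np.clip((Z[ii] * Z[jj]).sum(axis=1), -1.0, 1.0)
    names = np.array(members)
    return NullDistribution(
        species_set=projection.species_set,
        values=values,
        pair_a=tuple(names[ii]),
        pair_b=tuple(names[jj]),
    )


def _species_set_seed(seed: int, species_set: frozenset) -> np.random.SeedSequence:
    h = hashlib.sha256(",".join(sorted(species_set)).encode()).digest()
    return np.random.SeedSequence([seed, int.from_bytes(h[:4], "big") % (2**31)])


class ERCAnalysis:
    """Stateful ERC computation over a universe of branch-rate vectors.

    Holds the master topology, lazily builds one projection table and one
    null distribution per unique species set (cache keyed by the frozen
    species set, least-recently-used eviction beyond ``max_cached``), and
    scores gene pairs on demand.  ``background`` restricts the genes used
    to estimate the expected tree without restricting whose residuals are
    computed (the reproductive-background reanalysis mode).
    """

    def __init__(
        self,
        vectors: Sequence[BranchRateVector],
        tree: Phylogeny,
        *,
        min_species: int = MIN_SPECIES_DEFAULT,
        winsor_bound: float = WINSOR_BOUND_DEFAULT,
        n_null_pairs: int = NULL_PAIRS_DEFAULT,
        seed: int = 0,
        alternative: str = "greater",
        background: Optional[GeneSet] = None,
        method: str = "ratio",
        max_cached: int = 2048,
    ):
        ids = [v.gene_id for v in vectors]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in universe")
        self._vectors: Dict[str, BranchRateVector] = {
            v.gene_id: v for v in vectors
        }
        self.universe: Tuple[BranchRateVector, ...] = tuple(vectors)
        self.tree = tree
        self.cache = PruneCache(tree)
        self.min_species = min_species
        self.winsor_bound = winsor_bound
        self.n_null_pairs = n_null_pairs
        self.seed = seed
        self.alternative = alternative
        self.background = background
        self.method = method
        self.max_cached = max_cached
        self._projections: "OrderedDict[frozenset, ProjectionTable]" = OrderedDict()
        self._nulls: Dict[frozenset, NullDistribution] = {}

    def vector(self, gene_id: str) -> BranchRateVector:
        try:
            return self._vectors[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    @property
    def gene_ids(self) -> Tuple[str, ...]:
        return tuple(self._vectors)

    def projection(self, species_set: Iterable[str]) -> ProjectionTable:
        S = frozenset(species_set)
        if S in self._projections:
            self._projections.move_to_end(S)
            return self._projections[S]
        table = build_projection(
            S,
            self.universe,
            cache=self.cache,
            winsor_bound=self.winsor_bound,
            min_species=self.min_species,
            background=(
                set(self.background.members) if self.background else None
            ),
            background_name=self.background.name if self.background else "all",
            method=self.method,
        )
        self._projections[S] = table
        while len(self._projections) > self.max_cached:
            self._projections.popitem(last=False)
        return table

    def null(self, species_set: Iterable[str]) -> NullDistribution:
        S = frozenset(species_set)
        if S not in self._nulls:
            rng = np.random.default_rng(_species_set_seed(self.seed, S))
            self._nulls[S] = build_null(
                self.projection(S), n_pairs=self.n_null_pairs, rng=rng
            )
        return self._nulls[S]

    def pair(self, gene_a: str, gene_b: str) -> ERCResult:
        """Score one unordered gene pair on its shared species set."""
        if gene_a == gene_b:
            raise ValueError("cannot correlate a gene with itself")
        # canonical order so the result is exactly symmetric in (a, b)
        gene_a, gene_b = sorted((gene_a, gene_b))
        va, vb = self.vector(gene_a), self.vector(gene_b)
        S = va.species_set & vb.species_set
        if len(S) < self.min_species:
            raise PairSkipped(
                gene_a, gene_b,
                f"shared species {len(S)} below minimum {self.min_species}",
            )
        table = self.projection(S)
        ra = table.residuals.get(gene_a)
        rb = table.residuals.get(gene_b)
        if ra is None or rb is None:
            raise PairSkipped(gene_a, gene_b, "zero-norm branch vector")
        try:
            r = erc_value(ra, rb)
        except UndefinedCorrelationError:
            raise PairSkipped(gene_a, gene_b, "constant residual vector")
        p = empirical_pvalue(r, self.null(S), alternative=self.alternative)
        return ERCResult(
            gene_a=gene_a,
            gene_b=gene_b,
            shared_set=frozenset(S),
            n_branches=len(ra),
            r=r,
            p_emp=p,
        )

    def matrix(self, genes: Optional[Iterable[str]] = None):
        """All unordered pairs with admissible intersections.

        Returns ``(results, skipped)``; skipped pairs carry their reason.
        """
        ids = list(genes.members if isinstance(genes, GeneSet) else genes or self.gene_ids)
        results: List[ERCResult] = []
        skipped: List[PairSkipped] = []
        for a, b in itertools.combinations(ids, 2):
            try:
                results.append(self.pair(a, b))
            except PairSkipped as exc:
                skipped.append(exc)
        return results, skipped


def erc_matrix(genes, analysis: ERCAnalysis):
    """Module-level alias for :meth:`ERCAnalysis.matrix`."""
    return analysis.matrix(genes)


def write_erc_table(results: Sequence[ERCResult], path) -> None:
    """TSV: gene_a, gene_b, n_species, n_branches, r, p_emp."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tn_species\tn_branches\tr\tp_emp\n")
        for res in results:
            fh.write(
                f"{res.gene_a}\t{res.gene_b}\t{res.n_species}\t"
                f"{res.n_branches}\t{res.r:.17g}\t{res.p_emp:.17g}\n"
            )
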