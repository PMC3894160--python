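"""Species-matched permutation test for elevated mean ERC in a gene set.

The observed statistic is the mean ERC over all admissible pairs of the
tested set.  Each permutation replicate rebuilds that mean by replacing
every observed pair slot with an ERC value drawn uniformly from background
pairs of the *same species set* as that slot, which controls for the
dependence of ERC distributions on species coverage.  The p-value is the
add-one proportion of replicate means at or above the observed mean, so
its granularity is 1/(n_perm + 1).

Values are sampled independently across slots and replicates (no
within-replicate exclusivity).  A whole-set resampling mode
(``mode="resample_sets"``) draws random gene sets of the same size instead,
for sensitivity analysis.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .erc import ERCAnalysis, ERCResult, PairSkipped
from .io import GeneSet

__all__ = ["PermutationResult", "set_mean_erc", "permutation_test"]

N_PERM_DEFAULT = 10_000


@dataclass(eq=False)
class PermutationResult:
    """Outcome of one species-matched permutation test."""

    set_name: str
    observed_mean: float
    n_pairs_used: int
    n_skipped_pairs: int
    n_perm: int
    p_perm: float
    perm_mean: float
    perm_sd: float
    perm_quantiles: Dict[float, float]
    n_fallback_slots: int = 0
    mode: str = "resample_values"

    def __str__(self) -> str:  # human-readable report line
        return (
            f"{self.set_name}: mean ERC {self.observed_mean:.4f} over "
            f"{self.n_pairs_used} pairs; permutation p = {self.p_perm:.6g} "
            f"({self.n_perm} replicates, null mean {self.perm_mean:.4f} "
            f"+/- {self.perm_sd:.4f})"
        )


def _member_ids(members) -> List[str]:
    return list(members.members if isinstance(members, GeneSet) else members)


def set_mean_erc(members, results: Sequence[ERCResult]) -> Tuple[float, int]:
    """Arithmetic mean of ERC over all pairs within ``members`` present in
    a precomputed result list; returns ``(mean, n_pairs_used)``."""
    ids = set(_member_ids(members))
    rs = [
        res.r
        for res in results
        if res.gene_a in ids and res.gene_b in ids and res.gene_a != res.gene_b
    ]
    if not rs:
        raise ValueError("no admissible pairs within the tested set")
    return float(np.mean(rs)), len(rs)


def permutation_test(
    members,
    analysis: ERCAnalysis,
    n_perm: int = N_PERM_DEFAULT,
    seed: int = 0,
    set_name: Optional[str] = None,
    exclude_members: bool = False,
    mode: str = "resample_values",
) -> PermutationResult:
    """Test a gene set for elevated mean pairwise ERC.

    ``exclude_members`` removes background pairs touching the tested set
    from the sampling pools.  If a slot's species set has no background
    pairs, the nearest-size species-matched pool is used with a warning.
    """
    ids = _member_ids(members)
    if isinstance(members, GeneSet) and set_name is None:
        set_name = members.name
    set_name = set_name or "unnamed"
    if len(ids) < 2:
        raise ValueError("tested set needs at least 2 members")
    if mode not in ("resample_values", "resample_sets"):
        raise ValueError(f"unknown mode {mode!r}")

    slot_r: List[float] = []
    slot_sets: List[frozenset] = []
    n_skipped = 0
    for a, b in itertools.combinations(ids, 2):
        try:
            res = analysis.pair(a, b)
        except PairSkipped:
            n_skipped += 1
            continue
        slot_r.append(res.r)
        slot_sets.append(res.shared_set)
    if not slot_r:
        raise ValueError("no admissible pairs within the tested set")
    observed = float(np.mean(slot_r))
    rng = np.random.default_rng(seed)

    if mode == "resample_sets":
        means = _resample_sets_null(ids, analysis, n_perm, rng)
        n_fallback = 0
    else:
        pools: Dict[frozenset, np.ndarray] = {}
        member_set = set(ids)
        for S in dict.fromkeys(slot_sets):
            null = analysis.null(S)
            vals = null.values
            if exclude_members:
                pa = np.array(null.pair_a)
                pb = np.array(null.pair_b)
                keep = ~(np.isin(pa, list(member_set)) | np.isin(pb, list(member_set)))
                vals = vals[keep]
            if len(vals):
                pools[S] = vals
        if not pools:
            raise ValueError("no species-matched background pairs available")
        n_fallback = 0
        sums = np.zeros(n_perm)
        for S in slot_sets:
            if S in pools:
                pool = pools[S]
            else:
                # nearest-size species-matched fallback
                alt = min(
                    pools,
                    key=lambda T: (abs(len(T) - len(S)), tuple(sorted(T))),
                )
                warnings.warn(
                    f"no background pairs for a {len(S)}-species slot; "
                    f"falling back to a {len(alt)}-species pool",
                    stacklevel=2,
                )
                pool = pools[alt]
                n_fallback += 1
            sums += pool[rng.integers(0, len(pool), size=n_perm)]
        means = sums / len(slot_sets)

    p = (1 + int((means >= observed).sum())) / (1 + n_perm)
    qs = {q: float(np.quantile(means, q)) for q in (0.025, 0.5, 0.975)}
    return PermutationResult(
        set_name=set_name,
        observed_mean=observed,
        n_pairs_used=len(slot_r),
        n_skipped_pairs=n_skipped,
        n_perm=n_perm,
        p_perm=p,
        perm_mean=float(means.mean()),
        perm_sd=float(means.std(ddof=1)) if n_perm > 1 else 0.0,
        perm_quantiles=qs,
        n_fallback_slots=n_fallback,
        mode=mode,
    )


def _resample_sets_null(
    ids: Sequence[str], analysis: ERCAnalysis, n_perm: int, rng
) -> np.ndarray:
    """Whole-set resampling: random same-size gene sets from the universe."""
    pool = [g for g in analysis.gene_ids]
    k = len(ids)
    if len(pool) < k:
        raise ValueError("universe smaller than the tested set")
    means = np.empty(n_perm)
    for t in range(n_perm):
        chosen = rng.choice(len(pool), size=k, replace=False)
        rs = []
        for a, b in itertools.combinations(sorted(chosen), 2):
            try:
                rs.append(analysis.pair(pool[a], pool[b]).r)
            except PairSkipped:
                continue
        means[t] = np.mean(rs) if rs else np.nan
    return means
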