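"""Candidate screening: nominate new members of a coevolving network.

Each candidate is scored against every query (known network) protein; a
candidate is selected when it shows a significant empirical p-value
(p < 0.05) with at least two queries, or a highly significant one
(p < 0.01) with at least one.  "Multiple" is operationalized as >= 2
queries, the minimal reading; the thresholds are parameters.  No
multiple-testing correction is applied: this is a prioritization screen on
raw empirical p-values, not inference.  Candidates with no admissible
query pair are reported untestable, never silently dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .erc import ERCAnalysis, PairSkipped
from .io import GeneSet

__all__ = [
    "QueryHit",
    "CandidateResult",
    "ScreenReport",
    "apply_selection_rule",
    "screen",
    "iterate_screen",
]

P_SIG_DEFAULT = 0.05
P_STRONG_DEFAULT = 0.01


@dataclass(frozen=True)
class QueryHit:
    query: str
    r: float
    p_emp: float
    n_species: int


@dataclass(eq=False)
class CandidateResult:
    """Per-candidate aggregation of query correlations."""

    candidate: str
    hits: Tuple[QueryHit, ...]  # sorted by p_emp ascending
    n_skipped_queries: int
    n_queries_sig: int
    min_p: float  # NaN when untestable
    testable: bool
    selected: bool
    reason: str  # multi_query | single_strong | none


def apply_selection_rule(
    query_pvalues: Mapping[str, Sequence[float]],
    p_sig: float = P_SIG_DEFAULT,
    p_strong: float = P_STRONG_DEFAULT,
) -> Dict[str, Tuple[bool, str]]:
    """Pure selection rule on a candidate -> list-of-p table.

    Selected iff at least two p-values are below ``p_sig`` or at least one
    is below ``p_strong``; the reason records which clause fired
    (``multi_query`` takes precedence).
    """
    out: Dict[str, Tuple[bool, str]] = {}
    for cand, ps in query_pvalues.items():
        ps = list(ps)
        n_sig = sum(p < p_sig for p in ps)
        strong = any(p < p_strong for p in ps)
        if n_sig >= 2:
            out[cand] = (True, "multi_query")
        elif strong:
            out[cand] = (True, "single_strong")
        else:
            out[cand] = (False, "none")
    return out


@dataclass(eq=False)
class ScreenReport:
    """Full screen outcome; iteration order follows the candidate pool."""

    rows: Tuple[CandidateResult, ...]
    p_sig: float
    p_strong: float
    removed_overlap: Tuple[str, ...] = ()

    @property
    def selected(self) -> Tuple[str, ...]:
        return tuple(r.candidate for r in self.rows if r.selected)

    @property
    def untestable(self) -> Tuple[str, ...]:
        return tuple(r.candidate for r in self.rows if not r.testable)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (candidate, query) pair, plus a
        single row for untestable candidates."""
        records = []
        for row in self.rows:
            if not row.hits:
                records.append(
                    dict(
                        candidate=row.candidate, query=None, n_species=np.nan,
                        r=np.nan, p_emp=np.nan, n_queries_sig=0,
                        min_p=np.nan, selected=False, reason="untestable",
                    )
                )
                continue
            for h in row.hits:
                records.append(
                    dict(
                        candidate=row.candidate, query=h.query,
                        n_species=h.n_species, r=h.r, p_emp=h.p_emp,
                        n_queries_sig=row.n_queries_sig, min_p=row.min_p,
                        selected=row.selected, reason=row.reason,
                    )
                )
        return pd.DataFrame.from_records(records)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(
                f"# selection rule: >=2 queries at p<{self.p_sig} "
                f"or >=1 query at p<{self.p_strong}\n"
            )
            df.to_csv(fh, sep="\t", index=False)


def _ids(x) -> List[str]:
    return list(x.members if isinstance(x, GeneSet) else x)


def screen(
    queries,
    candidates,
    analysis: ERCAnalysis,
    p_sig: float = P_SIG_DEFAULT,
    p_strong: float = P_STRONG_DEFAULT,
) -> ScreenReport:
    """Score every query x candidate pair and apply the selection rule.

    Candidates overlapping the query set are removed with a warning (a
    protein cannot nominate itself).
    """
    q_ids = _ids(queries)
    c_ids = _ids(candidates)
    overlap = tuple(c for c in c_ids if c in set(q_ids))
    if overlap:
        warnings.warn(
            f"removing {len(overlap)} candidate(s) overlapping the query set",
            stacklevel=2,
        )
        c_ids = [c for c in c_ids if c not in set(q_ids)]

    rows: List[CandidateResult] = []
    for cand in c_ids:
        hits: List[QueryHit] = []
        skipped = 0
        for q in q_ids:
            try:
                res = analysis.pair(q, cand)
            except PairSkipped:
                skipped += 1
                continue
            hits.append(
                QueryHit(query=q, r=res.r, p_emp=res.p_emp, n_species=res.n_species)
            )
        hits.sort(key=lambda h: (h.p_emp, h.query))
        if hits:
            ps = [h.p_emp for h in hits]
            selected, reason = apply_selection_rule(
                {cand: ps}, p_sig=p_sig, p_strong=p_strong
            )[cand]
            rows.append(
                CandidateResult(
                    candidate=cand,
                    hits=tuple(hits),
                    n_skipped_queries=skipped,
                    n_queries_sig=sum(p < p_sig for p in ps),
                    min_p=min(ps),
                    testable=True,
                    selected=selected,
                    reason=reason,
                )
            )
        else:
            rows.append(
                CandidateResult(
                    candidate=cand,
                    hits=(),
                    n_skipped_queries=skipped,
                    n_queries_sig=0,
                    min_p=math.nan,
                    testable=False,
                    selected=False,
                    reason="none",
                )
            )
    return ScreenReport(
        rows=tuple(rows), p_sig=p_sig, p_strong=p_strong,
        removed_overlap=overlap,
    )


def iterate_screen(
    new_hits,
    pool,
    analysis: ERCAnalysis,
    **kwargs,
) -> ScreenReport:
    """Second-ring screen: confirmed hits become the query set.

    With an empty hit list the report is empty; with the original queries
    it reproduces :func:`screen` exactly.
    """
    hits = _ids(new_hits) if new_hits is not None else []
    if not hits:
        return ScreenReport(
            rows=(), p_sig=kwargs.get("p_sig", P_SIG_DEFAULT),
            p_strong=kwargs.get("p_strong", P_STRONG_DEFAULT),
        )
    return screen(hits, pool, analysis, **kwargs)
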