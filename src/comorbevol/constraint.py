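"""Per-gene constrained-sequence fractions and rank-based set comparison.

Constrained elements (regions under mammalian purifying selection, each
with an element-level p-value) are filtered at a significance threshold,
merged, and intersected with gene footprints.  A gene's constrained
fraction is the number of its bases covered by significant elements
divided by its total footprint length.  Gene sets are compared on these
per-gene fractions with a Mann–Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io_tables import IntervalSet, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ConstraintProfile",
    "filter_elements",
    "constrained_fraction",
    "compare_sets_mw",
]


@dataclass
class ConstraintProfile:
    """Per-gene constrained base counts and fractions.

    ``frame`` is indexed by gene name with integer columns
    ``constrained_bases`` and ``total_bases`` plus ``fraction`` in
    [0, 1].  ``skipped`` lists input genes without a coordinate record.
    """

    frame: pd.DataFrame
    skipped: list[str]

    def fractions(self, genes=None) -> np.ndarray:
        if genes is None:
            return self.frame["fraction"].to_numpy()
        idx = self.frame.index.intersection(list(genes))
        return self.frame.loc[idx, "fraction"].to_numpy()


def filter_elements(elements: IntervalSet, p_threshold: float = 0.05) -> IntervalSet:
    """Keep elements with p-value <= threshold.

    Every element must carry a p-value; otherwise the caller should use
    the element set unfiltered.
    """
    if len(elements) == 0:
        return elements
    if elements.frame["pvalue"].isna().any():
        raise ValidationError(
            "elements without p-values; pass the set unfiltered instead of filtering"
        )
    kept = elements.frame[elements.frame["pvalue"] <= p_threshold].reset_index(
        drop=True
    )
    return IntervalSet(frame=kept) if len(kept) else _empty_like(elements)


def _empty_like(intervals: IntervalSet) -> IntervalSet:
    return IntervalSet(frame=intervals.frame.iloc[0:0].reset_index(drop=True))


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals on one sequence, as disjoint sorted runs."""
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [], []
    cur_s, cur_e = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:  # abutting intervals merge: half-open convention
            cur_e = max(cur_e, e)
        else:
            merged_s.append(cur_s)
            merged_e.append(cur_e)
            cur_s, cur_e = s, e
    merged_s.append(cur_s)
    merged_e.append(cur_e)
    return np.asarray(merged_s), np.asarray(merged_e)


def _overlap_length(
    gs: int, ge: int, merged_s: np.ndarray, merged_e: np.ndarray
) -> int:
    lo = np.clip(merged_s, gs, ge)
    hi = np.clip(merged_e, gs, ge)
    return int(np.maximum(hi - lo, 0).sum())


def constrained_fraction(
    genes: IntervalSet, elements: IntervalSet
) -> ConstraintProfile:
    """Constrained bases and fraction per gene.

    Elements are merged (union) per sequence before intersection so
    overlapping elements are never double counted.  A gene named in
    several intervals contributes the union of its intervals as its
    footprint.  Genes with zero-length footprints are impossible by the
    interval invariant (start < end); unnamed gene intervals get the
    positional name ``seq:start-end``.
    """
    gf = genes.frame.copy()
    unnamed = gf["name"] == ""
    gf.loc[unnamed, "name"] = (
        gf.loc[unnamed, "seq_id"].astype(str)
        + ":"
        + gf.loc[unnamed, "start"].astype(str)
        + "-"
        + gf.loc[unnamed, "end"].astype(str)
    )

    merged_by_seq: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if len(elements):
        for seq_id, grp in elements.frame.groupby("seq_id", sort=False):
            merged_by_seq[seq_id] = _merge_intervals(
                grp["start"].to_numpy(), grp["end"].to_numpy()
            )

    rows = []
    for gene, grp in gf.groupby("name", sort=True):
        total = 0
        covered = 0
        for seq_id, sub in grp.groupby("seq_id", sort=False):
            gs_merged, ge_merged = _merge_intervals(
                sub["start"].to_numpy(), sub["end"].to_numpy()
            )
            total += int((ge_merged - gs_merged).sum())
            if seq_id in merged_by_seq:
                ms, me = merged_by_seq[seq_id]
                for gs, ge in zip(gs_merged, ge_merged):
                    covered += _overlap_length(int(gs), int(ge), ms, me)
        if total == 0:
            raise ValidationError(f"gene {gene!r} has total footprint length 0")
        rows.append((gene, covered, total, covered / total))
    frame = pd.DataFrame(
        rows, columns=["gene", "constrained_bases", "total_bases", "fraction"]
    ).set_index("gene")
    return ConstraintProfile(frame=frame, skipped=[])


def compare_sets_mw(
    values_a,
    values_b,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann–Whitney U comparison of two value lists.

    Returns ``(U, p)`` with ``U`` the statistic for the first sample.
    Exact p-value when ``min(n_a, n_b) <= 8`` and the pooled values are
    tie-free; otherwise the normal approximation with midrank tie
    correction.  ``alternative`` is ``two-sided``, ``a-greater`` or
    ``a-less``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both value lists must be nonempty")
    alt = {"two-sided": "two-sided", "a-greater": "greater", "a-less": "less"}.get(
        alternative
    )
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative=alt, method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))
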