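"""Set-level selection statistics: mean(pN)/mean(pS) with a resampling
null, and Mann–Whitney contrasts of per-gene dN/dS ratios.

The ratio-of-means statistic summarizes recent (within-population)
purifying selection on a gene set: the mean non-synonymous polymorphism
count over the set divided by the mean synonymous count.  Because the
statistic is set-level, its null distribution is built by resampling:
subsets of the larger comparison set, matched in size to the smaller
set, are drawn repeatedly and the observed ratio of the smaller set is
compared to the resampled ratios (upper tail; ties count as extreme, so
the test is conservative and the p-value is never exactly 0 — a result
beyond every resample is reported as < 1/B).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_tables import GeneStatsTable
from .constraint import compare_sets_mw
from .setops import GeneSetPartition

logger = logging.getLogger(__name__)

__all__ = [
    "ResamplingResult",
    "ratio_of_means",
    "resampling_test",
    "run_panel_contrasts",
    "PANEL_CONTRASTS",
    "compare_dnds",
]


@dataclass
class ResamplingResult:
    """Outcome of one ratio-of-means resampling contrast."""

    observed_ratio: float
    null_ratios: np.ndarray
    p_value: float
    n_small: int
    n_large: int
    B: int
    seed: int
    direction: str = "upper"
    label: str = ""
    n_dropped_small: int = 0
    n_dropped_large: int = 0

    def __post_init__(self) -> None:
        self.null_ratios = np.asarray(self.null_ratios, dtype=float)
        if len(self.null_ratios) != self.B:
            raise ValueError("null_ratios length must equal B")

    @property
    def p_display(self) -> str:
        """Human-readable p; exceedances of every resample print as < 1/B."""
        return f"< {1.0 / self.B:g}" if self.p_value == 0.0 else f"{self.p_value:g}"

    def summary(self) -> dict:
        q = np.quantile(self.null_ratios, [0.025, 0.25, 0.5, 0.75, 0.975])
        return {
            "label": self.label,
            "observed_ratio": self.observed_ratio,
            "observed_ratio_inverse": (
                float("inf") if self.observed_ratio == 0 else 1.0 / self.observed_ratio
            ),
            "null_mean": float(self.null_ratios.mean()),
            "null_sd": float(self.null_ratios.std(ddof=1)),
            "null_quantiles": {
                "2.5%": q[0], "25%": q[1], "50%": q[2], "75%": q[3], "97.5%": q[4]
            },
            "p_value": self.p_value,
            "p_display": self.p_display,
            "direction": self.direction,
            "n_small": self.n_small,
            "n_large": self.n_large,
            "B": self.B,
            "seed": self.seed,
        }


def _set_stats(genes, stats: GeneStatsTable) -> tuple[np.ndarray, np.ndarray, int]:
    genes = sorted(set(genes))
    sub = stats.frame.reindex(genes)[["pN", "pS"]].dropna()
    dropped = len(genes) - len(sub)
    return sub["pN"].to_numpy(float), sub["pS"].to_numpy(float), dropped


def ratio_of_means(genes, stats: GeneStatsTable) -> float:
    """mean(pN over set) / mean(pS over set).

    Genes absent from the statistics table are dropped with a logged
    count.  Raises when the mean pS is zero (undefined ratio).
    """
    pn, ps, dropped = _set_stats(genes, stats)
    if dropped:
        logger.info("ratio_of_means: dropped %d genes missing from stats", dropped)
    if len(ps) == 0:
        raise ValueError("no genes with pN/pS statistics in the set")
    mean_ps = ps.mean()
    if mean_ps == 0:
        raise ZeroDivisionError("mean pS is zero; ratio undefined")
    return float(pn.mean() / mean_ps)


def resampling_test(
    small_set,
    large_set,
    stats: GeneStatsTable,
    B: int = 1000,
    seed: int = 0,
    *,
    with_replacement: bool = False,
    direction: str = "upper",
    label: str = "",
) -> ResamplingResult:
    """Compare a small gene set's ratio-of-means against a resampled null.

    Draws ``B`` subsets of size ``|small_set|`` from ``large_set``
    (without replacement by default), computes the ratio of means for
    each, and reports the upper-tail fraction
    ``#{null_ratio >= observed} / B`` (lower tail with
    ``direction="lower"``).  Ties count as extreme.
    """
    small = sorted(set(small_set))
    large = sorted(set(large_set))
    if len(small) > len(large):
        raise ValueError(
            f"small_set ({len(small)}) larger than large_set ({len(large)})"
        )
    if B < 100:
        raise ValueError("B must be at least 100")
    if direction not in ("upper", "lower"):
        raise ValueError(f"unknown direction {direction!r}")
    overlap = set(small) & set(large)
    if overlap:
        logger.info("resampling_test: sets share %d genes", len(overlap))

    observed = ratio_of_means(small, stats)
    pn_s, ps_s, drop_s = _set_stats(small, stats)

    sub = stats.frame.reindex(large)[["pN", "pS"]].dropna()
    drop_l = len(large) - len(sub)
    if drop_l:
        logger.info("resampling_test: dropped %d large-set genes missing stats", drop_l)
    pn = sub["pN"].to_numpy(float)
    ps = sub["pS"].to_numpy(float)
    k = len(pn_s)
    if k > len(pn):
        raise ValueError("after dropping missing genes, small set exceeds large set")

    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        if with_replacement:
            idx = rng.integers(0, len(pn), size=k)
        else:
            idx = rng.choice(len(pn), size=k, replace=False)
        mean_ps = ps[idx].mean()
        null[b] = np.inf if mean_ps == 0 else pn[idx].mean() / mean_ps

    if direction == "upper":
        p = float(np.count_nonzero(null >= observed) / B)
    else:
        p = float(np.count_nonzero(null <= observed) / B)
    return ResamplingResult(
        observed_ratio=observed,
        null_ratios=null,
        p_value=p,
        n_small=k,
        n_large=len(pn),
        B=B,
        seed=seed,
        direction=direction,
        label=label,
        n_dropped_small=drop_s,
        n_dropped_large=drop_l,
    )


# The four headline contrasts on the focal-gene partition:
# A: focal-only vs all shared; B: focal-only vs shared-in-cluster;
# C: focal-only + shared-in-cluster vs shared-out; D: focal-only vs shared-out.
PANEL_CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "A": (("focal_only",), ("focal_shared_in_cluster", "focal_shared_out_cluster")),
    "B": (("focal_only",), ("focal_shared_in_cluster",)),
    "C": (
        ("focal_only", "focal_shared_in_cluster"),
        ("focal_shared_out_cluster",),
    ),
    "D": (("focal_only",), ("focal_shared_out_cluster",)),
}


def run_panel_contrasts(
    partition: GeneSetPartition,
    stats: GeneStatsTable,
    B: int = 1000,
    seed: int = 0,
) -> list[ResamplingResult]:
    """Run the four panel contrasts A-D on a gene-set partition.

    Each contrast compares two unions of partition roles; the smaller
    union is the resampled-against small set.  Contrasts with an empty
    side are skipped with a warning.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(PANEL_CONTRASTS))]
    results = []
    for (panel, (roles_x, roles_y)), sd in zip(PANEL_CONTRASTS.items(), seeds):
        set_x = frozenset().union(*(partition[r] for r in roles_x))
        set_y = frozenset().union(*(partition[r] for r in roles_y))
        if not set_x or not set_y:
            logger.warning("panel %s skipped: empty role set", panel)
            continue
        # the first side carries the elevated-ratio hypothesis; when it is
        # the larger side the smaller side is resampled against it and the
        # tail flips so every panel tests the same direction
        if len(set_x) <= len(set_y):
            small, large, direction = set_x, set_y, "upper"
        else:
            small, large, direction = set_y, set_x, "lower"
        res = resampling_test(
            small, large, stats, B=B, seed=sd, direction=direction,
            label=f"panel_{panel}",
        )
        results.append(res)
    return results


def compare_dnds(set_a, set_b, stats: GeneStatsTable) -> tuple[float, float]:
    """Mann–Whitney comparison of per-gene dN/dS between two gene sets.

    Genes with missing dN/dS are dropped with a logged count; each set
    must retain at least 2 genes.
    """
    if "dnds" not in stats.frame.columns:
        raise ValueError("stats table has no dnds column")
    vals = []
    for name, genes in (("a", set_a), ("b", set_b)):
        genes = sorted(set(genes))
        v = stats.frame.reindex(genes)["dnds"].dropna().to_numpy(float)
        dropped = len(genes) - len(v)
        if dropped:
            logger.info("compare_dnds: dropped %d set-%s genes lacking dN/dS", dropped, name)
        if len(v) < 2:
            raise ValueError(f"set {name} has fewer than 2 genes with dN/dS")
        vals.append(v)
    return compare_sets_mw(vals[0], vals[1], alternative="two-sided")
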