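"""Binary-distance Ward.D2 clustering of disorders with bootstrap support.

Disorders are clustered on the binary (asymmetric Jaccard) distance
between their gene-membership rows.  Cluster support comes in two
flavours:

* BP — the ordinary bootstrap probability, the fraction of replicate
  trees (gene columns resampled with replacement) containing a node's
  exact leaf set;
* AU — the approximately unbiased p-value from the multiscale
  bootstrap: BP is measured at several resample sizes ``round(r * n)``
  for a grid of scales ``r``, the probit-transformed values
  ``z(r) = Phi^-1(1 - BP(r))`` are fitted with the two-parameter curve
  ``z(r) = v * sqrt(r) + c / sqrt(r)`` by weighted least squares, and
  ``AU = 1 - Phi(v - c)``.

``v`` estimates the signed distance of the data from the boundary of
the region where the cluster appears, and ``c`` the boundary's
curvature; AU corrects the ordinary bootstrap's curvature bias.  The
standard error of AU follows from the WLS covariance by the delta
method.

The agglomeration uses the Ward.D2 criterion (Lance–Williams update on
squared dissimilarities, heights reported on the original scale) with a
deterministic lowest-index tie-break so that replicate trees are
reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .setops import PresenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MergeTree",
    "NodeSupport",
    "SupportedDendrogram",
    "DEFAULT_SCALES",
    "binary_distance",
    "ward_cluster",
    "multiscale_bootstrap",
    "plain_bootstrap",
    "significant_clusters",
    "to_newick",
]

DEFAULT_SCALES: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))


# ---------------------------------------------------------------------------
# distance


def binary_distance(matrix: PresenceMatrix) -> np.ndarray:
    """Pairwise binary distance between disorder rows.

    ``d(x, y) = (b + c) / (a + b + c)`` where ``a`` counts genes present
    in both disorders and ``b``, ``c`` genes present in exactly one;
    genes absent from both are ignored (R ``dist(method="binary")``).
    A pair sharing no genes at all gets ``d = 0`` with a warning.
    """
    if len(matrix.disorders) < 2:
        raise ValueError("need at least 2 disorders")
    return _binary_distance_values(matrix.values.astype(bool))


def _binary_distance_values(rows: np.ndarray) -> np.ndarray:
    rows = rows.astype(np.float64)
    inter = rows @ rows.T
    sizes = rows.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    empty = union == 0
    if empty.any() and empty[~np.eye(len(rows), dtype=bool)].any():
        warnings.warn("disorder pair with no genes in either; distance set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(empty, 0.0, (union - inter) / np.where(empty, 1.0, union))
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# Ward.D2 agglomeration


@dataclass(frozen=True)
class _Merge:
    left: int
    right: int
    height: float
    leafset: frozenset[str]


@dataclass
class MergeTree:
    """Binary merge tree over labelled leaves.

    ``merges[k]`` joins the clusters with ids ``left`` and ``right``
    (ids 0..n-1 are leaves in label order; id n+k is the k-th merge) at
    ``height`` on the original dissimilarity scale.
    """

    leaves: list[str]
    merges: list[_Merge]

    def internal_leafsets(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes, in merge order (root last)."""
        return [m.leafset for m in self.merges]

    @property
    def root_leafset(self) -> frozenset[str]:
        return frozenset(self.leaves)


def ward_cluster(dist: np.ndarray, labels: list[str] | None = None) -> MergeTree:
    """Agglomerate with the Ward.D2 criterion.

    Lance–Williams recurrence on squared dissimilarities,
    ``D(ij,k)^2 = [(n_i+n_k) D(i,k)^2 + (n_j+n_k) D(j,k)^2 - n_k D(i,j)^2]
    / (n_i+n_j+n_k)``, heights reported as the (unsquared) merge
    dissimilarity.  Ties merge the lexicographically smallest id pair.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if labels is None:
        labels = [str(i) for i in range(n)]

    sq = dist.astype(float) ** 2
    # active cluster bookkeeping: id -> (position in sq, size, leafset)
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    leafsets = {i: frozenset([labels[i]]) for i in range(n)}
    # grow sq to hold all 2n-1 clusters
    big = np.full((2 * n - 1, 2 * n - 1), np.inf)
    big[:n, :n] = sq
    merges: list[_Merge] = []
    next_id = n
    for _ in range(n - 1):
        best = (np.inf, -1, -1)
        for ai in range(len(ids)):
            i = ids[ai]
            for aj in range(ai + 1, len(ids)):
                j = ids[aj]
                d2 = big[i, j]
                if d2 < best[0] - 1e-15 or (
                    abs(d2 - best[0]) <= 1e-15 and (i, j) < (best[1], best[2])
                ):
                    best = (d2, i, j)
        d2, i, j = best
        new = next_id
        next_id += 1
        ni, nj = sizes[i], sizes[j]
        for k in ids:
            if k in (i, j):
                continue
            nk = sizes[k]
            upd = ((ni + nk) * big[i, k] + (nj + nk) * big[j, k] - nk * d2) / (
                ni + nj + nk
            )
            big[new, k] = big[k, new] = upd
        sizes[new] = ni + nj
        leafsets[new] = leafsets[i] | leafsets[j]
        ids = [k for k in ids if k not in (i, j)] + [new]
        merges.append(
            _Merge(left=i, right=j, height=float(np.sqrt(max(d2, 0.0))), leafset=leafsets[new])
        )
    return MergeTree(leaves=list(labels), merges=merges)


# ---------------------------------------------------------------------------
# bootstrap support


@dataclass
class NodeSupport:
    """Support annotation for one internal node of the observed tree."""

    leafset: frozenset[str]
    height: float
    bp: float
    au: float
    au_se: float
    v: float
    c: float
    degenerate: bool
    fit_curve: pd.DataFrame  # columns: scale, m, bp, z_obs, z_fit


@dataclass
class SupportedDendrogram:
    """Observed disorder tree with per-node BP/AU support."""

    tree: MergeTree
    nodes: list[NodeSupport]
    n_boot: int
    scales: tuple[float, ...]
    seed: int

    def node(self, leafset: frozenset[str]) -> NodeSupport:
        for ns in self.nodes:
            if ns.leafset == leafset:
                return ns
        raise KeyError(f"no node with leafset {sorted(leafset)}")

    def diagnostics(self) -> pd.DataFrame:
        rows = [
            {
                "leafset": ",".join(sorted(ns.leafset)),
                "size": len(ns.leafset),
                "height": ns.height,
                "bp": ns.bp,
                "au": ns.au,
                "au_se": ns.au_se,
                "v": ns.v,
                "c": ns.c,
                "degenerate": ns.degenerate,
            }
            for ns in self.nodes
        ]
        return pd.DataFrame(rows)

    def fit_curves(self) -> pd.DataFrame:
        frames = []
        for ns in self.nodes:
            f = ns.fit_curve.copy()
            f.insert(0, "leafset", ",".join(sorted(ns.leafset)))
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def _bootstrap_counts(
    values: np.ndarray,
    labels: list[str],
    observed: list[frozenset[str]],
    n_boot: int,
    m: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Count, per observed node, replicates whose tree contains its leafset."""
    n_genes = values.shape[1]
    obs_index = {ls: k for k, ls in enumerate(observed)}
    counts = np.zeros(len(observed), dtype=np.int64)
    bools = values.astype(bool)
    for _ in range(n_boot):
        idx = rng.integers(0, n_genes, size=m)
        rep = bools[:, idx]
        d = _binary_distance_values(rep)
        tree = ward_cluster(d, labels)
        for ls in tree.internal_leafsets():
            k = obs_index.get(ls)
            if k is not None:
                counts[k] += 1
    return counts


def multiscale_bootstrap(
    matrix: PresenceMatrix,
    n_boot: int = 1000,
    scales: tuple[float, ...] | list[float] = DEFAULT_SCALES,
    seed: int = 0,
) -> SupportedDendrogram:
    """Cluster disorders and attach multiscale-bootstrap AU/BP support.

    For each scale ``r`` draws ``n_boot`` resamples of
    ``round(r * n_genes)`` gene columns with replacement, re-clusters,
    and records per observed node the fraction of replicate trees
    containing its leaf set.  Fits ``z(r) = v sqrt(r) + c / sqrt(r)`` on
    the probit scale by WLS (weights from the binomial variance of BP
    propagated through the probit transform) and reports
    ``AU = 1 - Phi(v - c)`` with a delta-method standard error.

    Nodes never (or always) recovered at every scale have AU pinned to
    0 (or 1) with zero SE and ``degenerate=True``.
    """
    scales = tuple(float(r) for r in scales)
    if len(scales) < 3:
        raise ValueError("need at least 3 scales to fit the two-parameter curve")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if any(r <= 0 for r in scales):
        raise ValueError("scales must be positive")

    dist = binary_distance(matrix)
    tree = ward_cluster(dist, matrix.disorders)
    observed = tree.internal_leafsets()
    heights = {m.leafset: m.height for m in tree.merges}
    n_genes = len(matrix.genes)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(scales))
    bp_counts = np.zeros((len(observed), len(scales)), dtype=np.int64)
    ms = []
    for si, (r, cs) in enumerate(zip(scales, child_seeds)):
        m = max(2, int(round(r * n_genes)))
        ms.append(m)
        rng = np.random.default_rng(cs)
        bp_counts[:, si] = _bootstrap_counts(
            matrix.values, matrix.disorders, observed, n_boot, m, rng
        )

    r_arr = np.asarray(scales)
    nodes = []
    for k, ls in enumerate(observed):
        ns = _fit_node(ls, heights[ls], bp_counts[k], r_arr, np.asarray(ms), n_boot)
        nodes.append(ns)
    return SupportedDendrogram(
        tree=tree, nodes=nodes, n_boot=n_boot, scales=scales, seed=seed
    )


def _fit_node(
    leafset: frozenset[str],
    height: float,
    counts: np.ndarray,
    scales: np.ndarray,
    ms: np.ndarray,
    n_boot: int,
) -> NodeSupport:
    bp_raw = counts / n_boot
    # index of the scale closest to 1 reports the headline BP
    i1 = int(np.argmin(np.abs(scales - 1.0)))
    bp_at_1 = float(bp_raw[i1])

    if (counts == 0).all() or (counts == n_boot).all():
        au = 0.0 if (counts == 0).all() else 1.0
        curve = pd.DataFrame(
            {"scale": scales, "m": ms, "bp": bp_raw, "z_obs": np.nan, "z_fit": np.nan}
        )
        return NodeSupport(
            leafset=leafset,
            height=height,
            bp=bp_at_1,
            au=au,
            au_se=0.0,
            v=np.nan,
            c=np.nan,
            degenerate=True,
            fit_curve=curve,
        )

    eps = 0.5 / n_boot
    bp = np.clip(bp_raw, eps, 1.0 - eps)
    z = norm.ppf(1.0 - bp)
    # var(z) = var(BP) / phi(z)^2 with var(BP) = BP (1 - BP) / n_boot
    w = n_boot * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    beta = np.linalg.solve(xtwx, WX.T @ z)
    cov = np.linalg.inv(xtwx)
    v, c = float(beta[0]), float(beta[1])
    au = float(1.0 - norm.cdf(v - c))
    var_vc = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    au_se = float(norm.pdf(v - c) * np.sqrt(max(var_vc, 0.0)))
    z_fit = X @ beta
    curve = pd.DataFrame(
        {"scale": scales, "m": ms, "bp": bp_raw, "z_obs": z, "z_fit": z_fit}
    )
    return NodeSupport(
        leafset=leafset,
        height=height,
        bp=bp_at_1,
        au=au,
        au_se=au_se,
        v=v,
        c=c,
        degenerate=False,
        fit_curve=curve,
    )


def plain_bootstrap(
    matrix: PresenceMatrix, n_boot: int = 1000, seed: int = 0
) -> dict[frozenset[str], float]:
    """Ordinary bootstrap proportions (resample size = n_genes).

    Independent of :func:`multiscale_bootstrap`'s scale machinery; used
    to cross-check that BP at scale ``r = 1`` is the plain bootstrap
    proportion.
    """
    dist = binary_distance(matrix)
    tree = ward_cluster(dist, matrix.disorders)
    observed = tree.internal_leafsets()
    rng = np.random.default_rng(seed)
    n_genes = len(matrix.genes)
    counts = np.zeros(len(observed), dtype=np.int64)
    obs_index = {ls: k for k, ls in enumerate(observed)}
    bools = matrix.values.astype(bool)
    for _ in range(n_boot):
        cols = rng.integers(0, n_genes, size=n_genes)
        d = _binary_distance_values(bools[:, cols])
        rep = ward_cluster(d, matrix.disorders)
        for ls in rep.internal_leafsets():
            k = obs_index.get(ls)
            if k is not None:
                counts[k] += 1
    return {ls: counts[k] / n_boot for ls, k in obs_index.items()}


def significant_clusters(
    dendrogram: SupportedDendrogram, alpha: float = 0.15
) -> list[frozenset[str]]:
    """Maximal non-root nodes with AU >= 1 - alpha.

    The root (all leaves) is excluded: it is contained in every
    replicate tree by construction, so its support is uninformative.
    Nested significant nodes are collapsed to the largest.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    threshold = 1.0 - alpha
    root = dendrogram.tree.root_leafset
    candidates = [
        ns.leafset
        for ns in dendrogram.nodes
        if ns.au >= threshold and ns.leafset != root
    ]
    candidates.sort(key=len, reverse=True)
    maximal: list[frozenset[str]] = []
    for ls in candidates:
        if not any(ls < kept for kept in maximal):
            maximal.append(ls)
    return maximal


def to_newick(dendrogram: SupportedDendrogram) -> str:
    """Newick export with ``au:bp`` node labels as integer percentages."""
    tree = dendrogram.tree
    support = {ns.leafset: ns for ns in dendrogram.nodes}
    n = len(tree.leaves)
    reprs: dict[int, str] = {i: tree.leaves[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for k, m in enumerate(tree.merges):
        node_id = n + k
        ns = support[m.leafset]
        label = f"{round(100 * ns.au)}:{round(100 * ns.bp)}"
        bl = m.height - heights[m.left], m.height - heights[m.right]
        reprs[node_id] = (
            f"({reprs[m.left]}:{max(bl[0], 0.0):.6g},"
            f"{reprs[m.right]}:{max(bl[1], 0.0):.6g}){label}"
        )
        heights[node_id] = m.height
    return reprs[2 * n - 2] + ";"
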