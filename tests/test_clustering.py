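import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from comorbevol import SimulationConfig, build_presence_matrix, gen_association_matrix
from comorbevol.clustering import (
    MergeTree,
    NodeSupport,
    SupportedDendrogram,
    _fit_node,
    binary_distance,
    multiscale_bootstrap,
    plain_bootstrap,
    significant_clusters,
    to_newick,
    ward_cluster,
)
from comorbevol.setops import PresenceMatrix


def matrix_from_rows(rows, disorders=None):
    rows = np.asarray(rows, dtype=np.int8)
    disorders = disorders or [f"d{i}" for i in range(rows.shape[0])]
    genes = [f"g{j}" for j in range(rows.shape[1])]
    return PresenceMatrix(disorders=disorders, genes=genes, values=rows)


class TestBinaryDistance:
    def test_hand_enumerated_example(self):
        # rows (1,1,0) and (1,0,1): a=1 shared, b=c=1 each -> d = 2/3
        m = matrix_from_rows([[1, 1, 0], [1, 0, 1]])
        d = binary_distance(m)
        assert d[0, 1] == pytest.approx(2 / 3)

    def test_identical_rows_distance_zero(self):
        m = matrix_from_rows([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        assert binary_distance(m)[0, 1] == 0.0

    def test_disjoint_rows_distance_one(self):
        m = matrix_from_rows([[1, 1, 0], [0, 0, 1]])
        assert binary_distance(m)[0, 1] == 1.0

    def test_double_absences_ignored(self):
        # a gene absent from both rows of a pair must not dilute their distance
        a = binary_distance(matrix_from_rows([[1, 1, 0], [1, 0, 1], [0, 1, 1]]))
        b = binary_distance(
            matrix_from_rows([[1, 1, 0, 0], [1, 0, 1, 0], [0, 1, 1, 1]])
        )
        assert a[0, 1] == b[0, 1]

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(0)
        rows = (rng.random((5, 30)) < 0.4).astype(int)
        rows = rows[:, rows.sum(axis=0) > 0]
        m = matrix_from_rows(rows)
        d = binary_distance(m)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)


class TestWardCluster:
    def test_clear_first_merge(self):
        d = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0.0]])
        tree = ward_cluster(d, ["A", "B", "C"])
        assert tree.merges[0].leafset == frozenset({"A", "B"})

    def test_two_leaves_single_merge_at_distance(self):
        tree = ward_cluster(np.array([[0.0, 0.7], [0.7, 0.0]]), ["A", "B"])
        assert len(tree.merges) == 1
        assert tree.merges[0].height == pytest.approx(0.7)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ward_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 4))
        d = squareform(pdist(pts))
        tree = ward_cluster(d)
        heights = [m.height for m in tree.merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    @pytest.mark.parametrize("seed", range(10))
    def test_leafsets_match_scipy_ward_oracle(self, seed):
        """Ward.D2 merges agree with scipy's ward linkage on tie-free data."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        pts = rng.normal(size=(n, 3))
        d = squareform(pdist(pts))
        tree = ward_cluster(d)
        lk = linkage(pdist(pts), method="ward")
        assert _leafsets(tree) == _scipy_leafsets(lk, n)


def _leafsets(tree: MergeTree) -> set[frozenset[int]]:
    return {frozenset(int(x) for x in ls) for ls in tree.internal_leafsets()}


def _scipy_leafsets(lk: np.ndarray, n: int) -> set[frozenset[int]]:
    sets = {i: frozenset([i]) for i in range(n)}
    out = set()
    for k, (a, b, _, _) in enumerate(lk):
        sets[n + k] = sets[int(a)] | sets[int(b)]
        out.add(sets[n + k])
    return out


class TestMultiscaleBootstrap:
    def test_constant_half_bp_gives_au_half(self):
        # BP = 0.5 at every scale -> z = 0 everywhere -> v = c = 0 -> AU = 0.5
        scales = np.arange(0.5, 1.5, 0.1)
        counts = np.full(len(scales), 500)
        ns = _fit_node(
            frozenset({"a", "b"}), 1.0, counts, scales,
            (scales * 100).astype(int), 1000,
        )
        assert ns.au == pytest.approx(0.5, abs=1e-9)
        assert ns.v == pytest.approx(0.0, abs=1e-9)
        assert ns.c == pytest.approx(0.0, abs=1e-9)

    def test_zero_curvature_makes_au_equal_predicted_bp(self):
        # when c = 0, AU = 1 - Phi(v) which is the fitted BP at scale 1
        from scipy.stats import norm

        scales = np.arange(0.5, 1.5, 0.1)
        v_true = 0.4
        bp = 1.0 - norm.cdf(v_true * np.sqrt(scales))
        counts = np.round(bp * 1000).astype(int)
        ns = _fit_node(
            frozenset({"a"}), 1.0, counts, scales,
            (scales * 100).astype(int), 1000,
        )
        assert ns.c == pytest.approx(0.0, abs=0.02)
        assert ns.au == pytest.approx(1.0 - norm.cdf(ns.v), abs=0.01)

    def test_degenerate_nodes_pinned_and_flagged(self):
        scales = np.arange(0.5, 1.5, 0.1)
        ms = (scales * 100).astype(int)
        always = _fit_node(frozenset({"a"}), 1.0, np.full(10, 1000), scales, ms, 1000)
        never = _fit_node(frozenset({"b"}), 1.0, np.zeros(10, int), scales, ms, 1000)
        assert (always.au, always.au_se, always.degenerate) == (1.0, 0.0, True)
        assert (never.au, never.au_se, never.degenerate) == (0.0, 0.0, True)

    def test_short_scale_grid_rejected(self, planted_matrix):
        with pytest.raises(ValueError, match="scales"):
            multiscale_bootstrap(planted_matrix, n_boot=100, scales=(0.9, 1.1), seed=0)

    def test_small_n_boot_rejected(self, planted_matrix):
        with pytest.raises(ValueError, match="n_boot"):
            multiscale_bootstrap(planted_matrix, n_boot=50, seed=0)

    def test_planted_blocks_recovered_with_high_au(self):
        cfg = SimulationConfig(seed=7, n_genes=200)
        assoc, truth = gen_association_matrix(cfg)
        matrix = build_presence_matrix(assoc)
        dendro = multiscale_bootstrap(matrix, n_boot=400, seed=11)
        leafsets = {ns.leafset: ns for ns in dendro.nodes}
        for block in truth.blocks:
            assert block in leafsets
            assert leafsets[block].au > 0.85

    def test_observed_tree_invariant_to_gene_column_order(self, planted_matrix):
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(planted_matrix.genes))
        shuffled = PresenceMatrix(
            disorders=planted_matrix.disorders,
            genes=[planted_matrix.genes[j] for j in perm],
            values=planted_matrix.values[:, perm],
        )
        d1 = multiscale_bootstrap(planted_matrix, n_boot=100, seed=3)
        d2 = multiscale_bootstrap(shuffled, n_boot=100, seed=3)
        assert set(d1.tree.internal_leafsets()) == set(d2.tree.internal_leafsets())

    def test_bp_at_scale_one_matches_plain_bootstrap(self):
        cfg = SimulationConfig(
            seed=13, n_genes=120,
            within_block_share_prob=0.6, between_block_share_prob=0.25,
        )
        assoc, _ = gen_association_matrix(cfg)
        matrix = build_presence_matrix(assoc)
        n_boot = 600
        dendro = multiscale_bootstrap(matrix, n_boot=n_boot, seed=21)
        plain = plain_bootstrap(matrix, n_boot=n_boot, seed=77)
        tol = 2.0 / np.sqrt(n_boot)
        for ns in dendro.nodes:
            assert abs(ns.bp - plain[ns.leafset]) < max(tol, 3 * np.sqrt(
                max(ns.bp * (1 - ns.bp), plain[ns.leafset] * (1 - plain[ns.leafset]))
                / n_boot) + tol / 2)

    def test_au_se_shrinks_like_inverse_sqrt_n_boot(self):
        cfg = SimulationConfig(
            seed=17, n_genes=120,
            within_block_share_prob=0.6, between_block_share_prob=0.3,
        )
        assoc, _ = gen_association_matrix(cfg)
        matrix = build_presence_matrix(assoc)
        se_small = _mean_se(multiscale_bootstrap(matrix, n_boot=150, seed=5))
        se_large = _mean_se(multiscale_bootstrap(matrix, n_boot=600, seed=5))
        ratio = se_small / se_large
        assert 1.4 < ratio < 2.9  # theoretical value 2 for a 4x n_boot increase


def _mean_se(dendro: SupportedDendrogram) -> float:
    ses = [ns.au_se for ns in dendro.nodes if not ns.degenerate]
    assert ses, "fixture produced only degenerate nodes"
    return float(np.mean(ses))


class TestSignificantClusters:
    def _dendro(self, au_by_leafset):
        labels = sorted({x for ls in au_by_leafset for x in ls})
        n = len(labels)
        dist = np.ones((n, n)) - np.eye(n)
        tree = ward_cluster(dist, labels)
        nodes = []
        for ls in tree.internal_leafsets():
            au = au_by_leafset.get(ls, 0.5)
            nodes.append(
                NodeSupport(
                    leafset=ls, height=1.0, bp=au, au=au, au_se=0.01,
                    v=0.0, c=0.0, degenerate=False,
                    fit_curve=None,
                )
            )
        return SupportedDendrogram(
            tree=tree, nodes=nodes, n_boot=100, scales=(0.5, 1.0, 1.4), seed=0
        )

    def test_threshold_inclusion_and_exclusion(self):
        d = self._dendro({frozenset("ab"): 0.90, frozenset("cd"): 0.80})
        found = significant_clusters(d, alpha=0.15)
        assert frozenset("ab") in found
        assert frozenset("cd") not in found

    def test_nested_significant_nodes_collapse_to_maximal(self, planted_matrix):
        dendro = multiscale_bootstrap(planted_matrix, n_boot=200, seed=9)
        found = significant_clusters(dendro, alpha=0.15)
        for a in found:
            for b in found:
                assert a == b or not (a < b)

    def test_root_excluded(self, planted_matrix):
        dendro = multiscale_bootstrap(planted_matrix, n_boot=100, seed=2)
        found = significant_clusters(dendro, alpha=0.999)
        assert dendro.tree.root_leafset not in found

    def test_alpha_bounds(self, planted_matrix):
        dendro = multiscale_bootstrap(planted_matrix, n_boot=100, seed=2)
        with pytest.raises(ValueError):
            significant_clusters(dendro, alpha=0.0)


class TestNewickExport:
    def test_newick_parses_and_preserves_leaves(self, planted_matrix):
        import dendropy

        dendro = multiscale_bootstrap(planted_matrix, n_boot=100, seed=4)
        nwk = to_newick(dendro)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == set(planted_matrix.disorders)
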