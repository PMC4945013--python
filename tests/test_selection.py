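import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from comorbevol import SimulationConfig, gen_association_matrix, gen_gene_stats
from comorbevol.selection import (
    PANEL_CONTRASTS,
    compare_dnds,
    ratio_of_means,
    resampling_test,
    run_panel_contrasts,
)
from comorbevol.setops import GeneSetPartition

from conftest import stats_from_arrays
from test_constraint import exact_mw_enumeration


class TestRatioOfMeans:
    def test_forced_arithmetic(self):
        stats = stats_from_arrays([2, 4], [1, 3])
        assert ratio_of_means(["g0", "g1"], stats) == pytest.approx(1.5)

    def test_all_zero_pn_gives_zero(self):
        stats = stats_from_arrays([0, 0, 0], [1, 2, 3])
        assert ratio_of_means(["g0", "g1", "g2"], stats) == 0.0

    def test_zero_mean_ps_rejected(self):
        stats = stats_from_arrays([1, 2], [0, 0])
        with pytest.raises(ZeroDivisionError):
            ratio_of_means(["g0", "g1"], stats)

    def test_missing_genes_dropped(self):
        stats = stats_from_arrays([2, 4], [1, 3])
        # the absent gene must not contribute
        assert ratio_of_means(["g0", "g1", "nope"], stats) == pytest.approx(1.5)

    def test_matches_independent_summation_oracle(self):
        rng = np.random.default_rng(8)
        pn = rng.poisson(3.0, 50).astype(float)
        ps = rng.poisson(5.0, 50).astype(float) + 1
        stats = stats_from_arrays(pn, ps)
        genes = [f"g{i}" for i in range(50)]
        # independent accumulation: sum(pN)/n divided by sum(pS)/n
        expected = (pn.sum() / 50) / (ps.sum() / 50)
        assert ratio_of_means(genes, stats) == pytest.approx(expected)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0.1, 50.0), st.integers(0, 2**31 - 1))
    def test_scale_equivariance_in_pn(self, k, seed):
        rng = np.random.default_rng(seed)
        pn = rng.poisson(2.0, 20).astype(float)
        ps = rng.poisson(4.0, 20).astype(float) + 1
        genes = [f"g{i}" for i in range(20)]
        base = ratio_of_means(genes, stats_from_arrays(pn, ps))
        scaled = ratio_of_means(genes, stats_from_arrays(pn * k, ps))
        assert scaled == pytest.approx(k * base, rel=1e-9)


class TestResamplingTest:
    def test_degenerate_identical_stats_give_p_one(self):
        n = 300
        stats = stats_from_arrays(np.full(n, 2.0), np.full(n, 4.0))
        genes = [f"g{i}" for i in range(n)]
        res = resampling_test(genes[:50], genes[50:], stats, B=100, seed=0)
        assert res.p_value == 1.0

    def test_observed_above_all_nulls_reports_below_one_over_b(self):
        rng = np.random.default_rng(1)
        n = 500
        ps = rng.poisson(5.0, n).astype(float) + 1
        pn = rng.poisson(0.2 * ps).astype(float)
        pn[:40] += 30.0  # push the small set's ratio far above any resample
        stats = stats_from_arrays(pn, ps)
        genes = [f"g{i}" for i in range(n)]
        res = resampling_test(genes[:40], genes[40:], stats, B=200, seed=3)
        assert res.p_value == 0.0
        assert res.p_display == "< 0.005"

    def test_small_set_larger_than_large_set_rejected(self):
        stats = stats_from_arrays([1] * 10, [2] * 10)
        genes = [f"g{i}" for i in range(10)]
        with pytest.raises(ValueError, match="larger"):
            resampling_test(genes[:7], genes[7:], stats, B=100, seed=0)

    def test_same_seed_reproduces_null_exactly(self):
        rng = np.random.default_rng(5)
        n = 400
        ps = rng.poisson(4.0, n).astype(float) + 1
        pn = rng.poisson(0.3 * ps).astype(float)
        stats = stats_from_arrays(pn, ps)
        genes = [f"g{i}" for i in range(n)]
        r1 = resampling_test(genes[:60], genes[60:], stats, B=150, seed=42)
        r2 = resampling_test(genes[:60], genes[60:], stats, B=150, seed=42)
        assert np.array_equal(r1.null_ratios, r2.null_ratios)
        assert r1.p_value == r2.p_value

    def test_with_replacement_flag_changes_null(self):
        rng = np.random.default_rng(6)
        n = 300
        ps = rng.poisson(4.0, n).astype(float) + 1
        pn = rng.poisson(0.3 * ps).astype(float)
        stats = stats_from_arrays(pn, ps)
        genes = [f"g{i}" for i in range(n)]
        without = resampling_test(genes[:50], genes[50:], stats, B=120, seed=7)
        withr = resampling_test(
            genes[:50], genes[50:], stats, B=120, seed=7, with_replacement=True
        )
        assert not np.array_equal(without.null_ratios, withr.null_ratios)

    def test_planted_elevated_ratio_detected(self):
        """Power at the analysis scale: omega 0.35 vs 0.25, n=262/779."""
        rng = np.random.default_rng(9)
        n_small, n_large = 262, 779
        ps = rng.poisson(5.0, n_small + n_large).astype(float) + 1
        pn = np.concatenate(
            [
                rng.poisson(0.35 * ps[:n_small]),
                rng.poisson(0.25 * ps[n_small:]),
            ]
        ).astype(float)
        stats = stats_from_arrays(pn, ps)
        genes = [f"g{i}" for i in range(n_small + n_large)]
        res = resampling_test(genes[:n_small], genes[n_small:], stats, B=1000, seed=1)
        assert res.observed_ratio > np.median(res.null_ratios)
        assert res.p_value < 0.05


class TestPanelContrasts:
    def _partition(self, sets):
        roles = {
            "focal_only": frozenset(),
            "focal_shared_in_cluster": frozenset(),
            "focal_shared_out_cluster": frozenset(),
            "cluster_non_focal": frozenset(),
            "outside_cluster": frozenset(),
        }
        roles.update({k: frozenset(v) for k, v in sets.items()})
        return GeneSetPartition(
            focal="F", cluster_members=frozenset({"F", "X"}), sets=roles
        )

    def test_planted_shift_is_one_directional_in_all_panels(self):
        rng = np.random.default_rng(12)
        only = [f"u{i}" for i in range(200)]
        shared_in = [f"s{i}" for i in range(400)]
        shared_out = [f"o{i}" for i in range(400)]
        genes = only + shared_in + shared_out
        ps = rng.poisson(5.0, len(genes)).astype(float) + 1
        omega = np.concatenate(
            [np.full(200, 0.35), np.full(800, 0.25)]
        )
        pn = rng.poisson(omega * ps).astype(float)
        stats = stats_from_arrays(pn, ps, genes=genes)
        part = self._partition(
            {
                "focal_only": only,
                "focal_shared_in_cluster": shared_in,
                "focal_shared_out_cluster": shared_out,
            }
        )
        results = run_panel_contrasts(part, stats, B=400, seed=3)
        assert {r.label for r in results} == {
            "panel_A", "panel_B", "panel_C", "panel_D",
        }
        # every panel points the same way: the focal-only-containing side
        # sits above the null built on the other side
        for r in results:
            med = np.median(r.null_ratios)
            if r.direction == "upper":
                assert r.observed_ratio > med
            else:
                assert r.observed_ratio < med
            assert r.p_value < 0.05

    def test_null_omega_rarely_significant(self):
        """With no omega difference, strong panel significance is rare."""
        hits = 0
        runs = 30
        for k in range(runs):
            rng = np.random.default_rng(1000 + k)
            only = [f"u{i}" for i in range(80)]
            shared = [f"s{i}" for i in range(320)]
            genes = only + shared
            ps = rng.poisson(5.0, 400).astype(float) + 1
            pn = rng.poisson(0.3 * ps).astype(float)
            stats = stats_from_arrays(pn, ps, genes=genes)
            part = self._partition(
                {"focal_only": only, "focal_shared_in_cluster": shared}
            )
            results = run_panel_contrasts(part, stats, B=200, seed=k)
            hits += any(r.p_value < 0.01 for r in results)
        assert hits / runs <= 0.25

    def test_empty_out_cluster_skips_panels_c_and_d(self):
        rng = np.random.default_rng(14)
        only = [f"u{i}" for i in range(120)]
        shared = [f"s{i}" for i in range(200)]
        genes = only + shared
        ps = rng.poisson(4.0, len(genes)).astype(float) + 1
        pn = rng.poisson(0.3 * ps).astype(float)
        stats = stats_from_arrays(pn, ps, genes=genes)
        part = self._partition(
            {"focal_only": only, "focal_shared_in_cluster": shared}
        )
        labels = {r.label for r in run_panel_contrasts(part, stats, B=150, seed=1)}
        assert labels == {"panel_A", "panel_B"}


class TestCompareDnds:
    def test_enumeration_example(self):
        stats = stats_from_arrays(
            [1] * 6, [1] * 6, dnds=[0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        )
        u, p = compare_dnds(["g0", "g1", "g2"], ["g3", "g4", "g5"], stats)
        u_or, p_or = exact_mw_enumeration([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert (u, p) == (pytest.approx(u_or), pytest.approx(p_or))
        assert u == 0 and p == pytest.approx(0.1)

    def test_identical_sets_p_one(self):
        stats = stats_from_arrays([1] * 4, [1] * 4, dnds=[0.1, 0.2, 0.3, 0.4])
        _, p = compare_dnds(["g0", "g1", "g2", "g3"], ["g0", "g1", "g2", "g3"], stats)
        assert p == pytest.approx(1.0)

    def test_planted_lognormal_shift_detected(self):
        rng = np.random.default_rng(15)
        n = 150
        dnds = np.concatenate(
            [rng.lognormal(-1.0 + 0.5, 0.5, n), rng.lognormal(-1.0, 0.5, n)]
        )
        stats = stats_from_arrays([1] * (2 * n), [1] * (2 * n), dnds=dnds)
        genes = [f"g{i}" for i in range(2 * n)]
        _, p = compare_dnds(genes[:n], genes[n:], stats)
        assert p < 0.01

    def test_underpopulated_set_rejected(self):
        stats = stats_from_arrays([1] * 3, [1] * 3, dnds=[0.1, np.nan, 0.3])
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_dnds(["g0", "g1"], ["g2"], stats)

    def test_missing_dnds_dropped(self):
        stats = stats_from_arrays(
            [1] * 6, [1] * 6, dnds=[0.1, 0.2, np.nan, 0.4, 0.5, 0.6]
        )
        u, _ = compare_dnds(["g0", "g1", "g2"], ["g3", "g4", "g5"], stats)
        assert u == 0  # only two values remain in set a, both below set b
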