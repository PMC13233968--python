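"""Error metrics, CIs, agreement, diagnostic metrics and paired tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pedqtc import evalstats as es


class TestErrorMetrics:
    def test_perfect(self):
        s = es.error_metrics([400.0, 420.0], [400.0, 420.0])
        assert (s.mae_ms.estimate, s.me_ms.estimate, s.sde_ms.estimate) == \
            (0.0, 0.0, 0.0)

    def test_sign_convention(self):
        """Uniform overestimation by 19.3 ms yields ME = -19.3."""
        truth = np.linspace(380, 500, 50)
        s = es.error_metrics(truth, truth + 19.3)
        assert s.me_ms.estimate == pytest.approx(-19.3)
        assert s.mae_ms.estimate == pytest.approx(19.3)
        assert s.sde_ms.estimate == pytest.approx(0.0, abs=1e-9)

    def test_hand_arithmetic(self):
        s = es.error_metrics([400.0, 420.0], [410.0, 415.0])
        assert s.mae_ms.estimate == pytest.approx(7.5)
        assert s.me_ms.estimate == pytest.approx(-2.5)
        assert s.sde_ms.estimate == pytest.approx(np.sqrt(112.5), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            es.error_metrics([], [])


class TestBootstrapCI:
    def test_constant_statistic(self):
        ci = es.bootstrap_ci(lambda x: 7.0, np.arange(100.0), n_boot=50)
        assert ci.ci_low == ci.ci_high == ci.estimate == 7.0

    def test_width_matches_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 10000)
        ci = es.bootstrap_ci(np.mean, x, n_boot=2000, seed=1)
        width = ci.ci_high - ci.ci_low
        expected = 2 * 1.96 * np.std(x) / np.sqrt(x.size)
        assert abs(width - expected) / expected < 0.15

    def test_seeded(self):
        x = np.random.default_rng(2).normal(size=500)
        a = es.bootstrap_ci(np.mean, x, n_boot=200, seed=3)
        b = es.bootstrap_ci(np.mean, x, n_boot=200, seed=3)
        assert a == b


class TestBlandAltman:
    def test_constant_shift(self):
        truth = np.linspace(380, 500, 100)
        fit = es.bland_altman(truth, truth + 12.0)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(-12.0, abs=1e-9)
        assert fit.loa_low_ms == pytest.approx(-12.0, abs=1e-9)
        assert fit.loa_high_ms == pytest.approx(-12.0, abs=1e-9)

    def test_injected_slope_recovered(self):
        rng = np.random.default_rng(1)
        truth = rng.normal(424, 28, 20000)
        preds = truth + 0.2 * (truth - 424.0)
        fit = es.bland_altman(truth, preds)
        assert fit.slope == pytest.approx(-0.2, abs=1e-6)
        assert fit.wald_p < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            es.bland_altman(np.full(10, 424.0), np.arange(10.0))


class TestDiagnosticMetrics:
    def test_hand_arithmetic(self):
        d = es.diagnostic_metrics(es.ContingencyTable(90, 100, 10, 800))
        assert d["sens"] == pytest.approx(0.9)
        assert d["spec"] == pytest.approx(800 / 900)
        assert d["plr"] == pytest.approx(8.1)
        assert d["nlr"] == pytest.approx(0.1125)
        assert not d["smoothed"]

    def test_smoothing_on_empty_cell(self):
        d = es.diagnostic_metrics(es.ContingencyTable(10, 20, 0, 170))
        assert d["smoothed"]
        assert d["sens"] == pytest.approx(10.5 / 11)
        assert d["nlr"] == pytest.approx((0.5 / 11) / (170.5 / 191), abs=5e-4)

    @settings(derandomize=True, max_examples=100)
    @given(tp=st.integers(1, 500), fp=st.integers(1, 500),
           fn=st.integers(1, 500), tn=st.integers(1, 500))
    def test_plr_nlr_relation(self, tp, fp, fn, tn):
        """plr > 1 iff nlr < 1 whenever sens + spec > 1."""
        d = es.diagnostic_metrics(es.ContingencyTable(tp, fp, fn, tn))
        if d["sens"] + d["spec"] > 1:
            assert d["plr"] > 1
            assert d["nlr"] < 1

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = 300
            gold = rng.random(n) < 0.2
            flag = rng.random(n) < 0.3
            t = es.contingency_from_labels(flag, gold)
            # brute-force recount
            assert t.tp == sum(1 for f, g in zip(flag, gold) if f and g)
            assert t.fn == sum(1 for f, g in zip(flag, gold) if not f and g)
            assert t.fp == sum(1 for f, g in zip(flag, gold) if f and not g)
            assert t.total == n


class TestProspectiveCI:
    def test_normal_approximation(self):
        ci = es.ci_prospective("sens", es.ContingencyTable(50, 10, 50, 90))
        assert ci.method == "normal"
        assert ci.ci_low == pytest.approx(0.402, abs=0.001)
        assert ci.ci_high == pytest.approx(0.598, abs=0.001)

    def test_boundary_uses_exact(self):
        ci = es.ci_prospective("sens", es.ContingencyTable(14, 10, 0, 176))
        assert ci.method == "exact_binomial"
        assert ci.estimate == 1.0
        assert ci.ci_low == pytest.approx(0.768, abs=0.005)
        assert ci.ci_high == 1.0

    def test_lr_with_zero_cell_is_finite(self):
        ci = es.ci_prospective("nlr", es.ContingencyTable(14, 28, 0, 158))
        assert ci.method == "log_normal"
        assert np.isfinite(ci.ci_low) and np.isfinite(ci.ci_high)
        assert ci.ci_low <= ci.estimate <= ci.ci_high


class TestMcNemar:
    def test_symmetric_discordance(self):
        a = np.array([True] * 5 + [False] * 5 + [True] * 40)
        b = np.array([False] * 5 + [True] * 5 + [True] * 40)
        res = es.mcnemar_test(a, b)
        assert res.p_value == 1.0
        assert res.test == "mcnemar_exact"

    def test_one_sided_discordance_exact_tail(self):
        a = np.array([True] * 10 + [True] * 30)
        b = np.array([False] * 10 + [True] * 30)
        res = es.mcnemar_test(a, b)
        assert res.p_value == pytest.approx(2 * 0.5 ** 10)

    def test_identical_classifiers(self):
        flags = np.random.default_rng(0).random(50) < 0.5
        res = es.mcnemar_test(flags, flags)
        assert res.p_value == 1.0


class TestLapAndGuPepe:
    def test_identical_classifiers_null(self):
        rng = np.random.default_rng(1)
        g = rng.random(400) < 0.3
        a = g ^ (rng.random(400) < 0.1)
        assert es.lap_predictive_value_test(a, a, g, "ppv").p_value == 1.0
        assert es.gu_pepe_lr_test(a, a, g, "plr").p_value == 1.0

    @pytest.mark.parametrize("which", ["lap", "gu_pepe"])
    def test_dominant_classifier_detected(self, which):
        rng = np.random.default_rng(2)
        n = 2000
        g = rng.random(n) < 0.3
        a = g ^ (rng.random(n) < 0.05)   # strictly better
        b = g ^ (rng.random(n) < 0.25)
        if which == "lap":
            res = es.lap_predictive_value_test(a, b, g, "ppv")
        else:
            res = es.gu_pepe_lr_test(a, b, g, "plr")
        assert res.p_value < 0.01
        assert res.estimate_a > res.estimate_b

    def test_no_qualifying_records_raises(self):
        g = np.array([True, False, True])
        never = np.zeros(3, dtype=bool)
        with pytest.raises(ValueError):
            es.lap_predictive_value_test(never, never, g, "ppv")

    def test_gu_pepe_smooths_degenerate_cells(self):
        g = np.array([True] * 20 + [False] * 80)
        a = np.array([True] * 20 + [False] * 80)   # perfect: zero FP
        b = np.array([True] * 18 + [False] * 2 + [True] * 5 + [False] * 75)
        res = es.gu_pepe_lr_test(a, b, g, "plr")
        assert "smoothed" in res.test
        assert np.isfinite(res.p_value)


class TestCompareErrorMetrics:
    def test_identical_estimators(self):
        truth = np.random.default_rng(0).normal(424, 20, 200)
        preds = truth + 3.0
        out = es.compare_error_metrics(truth, preds, preds)
        assert all(c.p_value == 1.0 for c in out)

    def test_constant_shift_detected_by_wilcoxon(self):
        rng = np.random.default_rng(1)
        truth = rng.normal(424, 20, 1000)
        a = truth + rng.normal(0, 5, 1000)
        b = a + 10.0
        out = {c.metric: c for c in es.compare_error_metrics(truth, a, b)}
        assert out["me"].p_value < 1e-6

    def test_variance_ratio_detected_by_bartlett(self):
        rng = np.random.default_rng(2)
        truth = np.zeros(500)
        a = rng.normal(0, 1, 500)
        b = rng.normal(0, 2, 500)
        out = {c.metric: c for c in es.compare_error_metrics(truth, a, b)}
        assert out["sde"].p_value < 1e-6

    def test_f1_difference_ci(self):
        rng = np.random.default_rng(3)
        truth = rng.normal(424, 30, 800)
        a = truth + rng.normal(0, 10, 800)
        out = es.compare_error_metrics(truth, a, a, n_boot=100,
                                       thresholds=(460.0,))
        f1 = [c for c in out if c.metric.startswith("f1")][0]
        assert f1.ci_low <= 0.0 <= f1.ci_high


class TestFairness:
    def test_injected_group_effect(self):
        rng = np.random.default_rng(4)
        n = 1200
        truth = rng.normal(424, 25, n)
        groups = np.repeat(["infant", "toddler", "school_age"], n // 3)
        noise = np.where(groups == "infant", 18.0, 8.0)
        preds = truth + rng.normal(0, 1, n) * noise
        res = es.fairness_mae_by_group(truth, preds, groups)
        maes = {g: m.estimate for g, m in res["per_group"].items()}
        assert max(maes, key=maes.get) == "infant"
        worst = [c for c in res["comparisons"] if "infant" in c.metric]
        assert all(c.p_value < 0.01 for c in worst)

    def test_single_group_no_comparisons(self):
        truth = np.random.default_rng(5).normal(424, 20, 100)
        res = es.fairness_mae_by_group(truth, truth + 1.0,
                                       np.repeat("all", 100))
        assert res["comparisons"] == []

    def test_small_group_flagged(self):
        truth = np.random.default_rng(6).normal(424, 20, 100)
        groups = np.array(["big"] * 90 + ["tiny"] * 10)
        res = es.fairness_mae_by_group(truth, truth + 1.0, groups)
        assert res["low_n_groups"] == ["tiny"]
        assert "tiny" not in res["per_group"]


class TestRaterConsensus:
    def test_identical_raters(self):
        m = np.tile([[420.0], [450.0]], (1, 3))
        algo, per_rater, keep = es.rater_consensus(m)
        np.testing.assert_array_equal(algo, [420.0, 450.0])
        np.testing.assert_array_equal(per_rater, m)

    def test_leave_one_out_arithmetic(self):
        algo, per_rater, _ = es.rater_consensus([[400.0, 410.0, 420.0]])
        assert algo[0] == pytest.approx(410.0)
        assert per_rater[0, 0] == pytest.approx(415.0)  # excludes rater 1
        assert per_rater[0, 2] == pytest.approx(405.0)

    def test_missing_rows_dropped_single_rater_rejected(self):
        m = np.array([[400.0, np.nan], [420.0, 430.0]])
        algo, _, keep = es.rater_consensus(m)
        assert algo.size == 1 and keep.tolist() == [False, True]
        with pytest.raises(ValueError):
            es.rater_consensus(np.array([[400.0], [420.0]]))


class TestErrorProfile:
    def test_perfect_predictions(self):
        truth = np.random.default_rng(0).uniform(380, 520, 200)
        by_bin, cumulative = es.error_profile(truth, truth, n_boot=50)
        assert (by_bin["mae_ms"] == 0).all()
        assert cumulative["fraction"].iloc[0] == 1.0

    def test_half_normal_mae(self):
        rng = np.random.default_rng(1)
        truth = rng.uniform(400, 450, 50000)
        preds = truth + rng.normal(0, 20, truth.size)
        by_bin, _ = es.error_profile(truth, preds, n_boot=20)
        expected = 20.0 * np.sqrt(2 / np.pi)
        big = by_bin[by_bin["n"] > 5000]
        assert np.allclose(big["mae_ms"], expected, rtol=0.05)

    def test_bin_convention(self):
        by_bin, _ = es.error_profile(np.array([460.0, 455.0, 465.0]),
                                     np.array([460.0, 455.0, 465.0]),
                                     n_boot=0 or 50)
        row = by_bin[by_bin["bin_low_ms"] == 460.0].iloc[0]
        assert row["n"] == 2  # 460.0 and 465.0 fall in [460, 470)
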