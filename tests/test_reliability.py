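"""Reliability statistics against brute-force and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lasertrace import (LaserTraceError, TrialReliability, compare_groups, icc,
                        normality_gate, reliability_by_condition, rm_anova,
                        sem_from_differences, speed_accuracy_correlation)
from lasertrace.reliability import holm_adjust, mean_squares

# small integer fixture used by several oracle comparisons
MATRIX_4x3 = np.array([
    [7.0, 9.0, 8.0],
    [5.0, 6.0, 4.0],
    [9.0, 12.0, 11.0],
    [3.0, 2.0, 4.0],
])


def brute_force_mean_squares(m):
    """Two-way mean squares via explicit elementwise sums of squares."""
    n, k = m.shape
    grand = m.sum() / (n * k)
    ss_rows = sum(k * (m[i].sum() / k - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (m[:, j].sum() / n - grand) ** 2 for j in range(k))
    ss_tot = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


class TestICC:
    def test_identical_trials_give_unity(self):
        m = np.tile([[10.0], [20.0], [30.0]], (1, 3))
        for form in ("consistency", "agreement"):
            value, ci = icc(m, form)
            assert value == 1.0 and ci == (1.0, 1.0)

    def test_matches_brute_force_sums_of_squares(self):
        msr, msc, mse = brute_force_mean_squares(MATRIX_4x3)
        n, k = MATRIX_4x3.shape
        expected_c = (msr - mse) / (msr + (k - 1) * mse)
        expected_a = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(MATRIX_4x3, "consistency")[0] == pytest.approx(expected_c, abs=1e-9)
        assert icc(MATRIX_4x3, "agreement")[0] == pytest.approx(expected_a, abs=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        m = rng.normal(70, 10, (15, 1)) + rng.normal(0, 5, (15, 3)) + [0.0, 1.5, 2.5]
        df = pd.DataFrame({"s": np.repeat(np.arange(15), 3),
                           "t": np.tile(np.arange(3), 15), "y": m.ravel()})
        ref = pg.intraclass_corr(df, targets="s", raters="t", ratings="y")
        ref = ref.set_index("Type")
        val_c, ci_c = icc(m, "consistency")
        val_a, ci_a = icc(m, "agreement")
        assert val_c == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-9)
        assert val_a == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        np.testing.assert_allclose(np.round(ci_c, 2), ref.loc["ICC(C,1)", "CI95"])
        np.testing.assert_allclose(np.round(ci_a, 2), ref.loc["ICC(A,1)", "CI95"])

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(7)
        vals = [icc(rng.normal(size=(200, 3)), "consistency")[0] for _ in range(20)]
        assert abs(np.mean(vals)) < 0.05

    def test_consistency_at_least_agreement_when_trial_effect_present(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            m = rng.normal(0, 1, (8, 3)) + rng.normal(0, 2, (8, 1)) + [0.0, 1.0, 2.0]
            ms = mean_squares(m)
            if ms.msc > ms.mse:
                assert icc(m, "consistency")[0] >= icc(m, "agreement")[0] - 1e-12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(LaserTraceError):
            icc(np.zeros((4, 3)))
        with pytest.raises(LaserTraceError):
            icc(MATRIX_4x3[:1])
        with pytest.raises(LaserTraceError):
            icc(MATRIX_4x3[:, :1])


class TestSEM:
    def test_identical_trials_zero(self):
        m = np.tile([[10.0], [20.0], [30.0]], (1, 3))
        sem, _ = sem_from_differences(m)
        assert sem == 0.0

    def test_sd_7_0711_gives_5(self):
        # consecutive differences [+5, -5]: SD = 7.0711, SEM = 5.0000
        m = np.array([[0.0, 5.0], [0.0, -5.0]])
        diffs = np.diff(m, axis=1).ravel()
        assert np.std(diffs, ddof=1) == pytest.approx(7.0711, abs=1e-4)
        assert sem_from_differences(m)[0] == pytest.approx(5.0, abs=1e-9)

    def test_shift_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(3)
        m = rng.normal(70, 10, (20, 3))
        base, _ = sem_from_differences(m)
        shifted, _ = sem_from_differences(m + 13.7)
        scaled, _ = sem_from_differences(m * -2.5)
        assert shifted == pytest.approx(base, rel=1e-12)
        assert scaled == pytest.approx(2.5 * base, rel=1e-12)

    def test_recovers_within_subject_sd(self):
        # trial scores = subject effect + N(0, 6): SEM estimates sigma_e
        rng = np.random.default_rng(99)
        ests = []
        for _ in range(50):
            m = rng.normal(70, 10, (50, 1)) + rng.normal(0, 6.0, (50, 3))
            ests.append(sem_from_differences(m)[0])
        assert np.mean(ests) == pytest.approx(6.0, rel=0.15)

    def test_mean_of_pairs_variant(self):
        sem_pooled, _ = sem_from_differences(MATRIX_4x3, method="pooled")
        sem_pairs, _ = sem_from_differences(MATRIX_4x3, method="mean_of_pairs")
        d = np.diff(MATRIX_4x3, axis=1)
        expected = np.mean([np.std(d[:, 0], ddof=1), np.std(d[:, 1], ddof=1)]) / np.sqrt(2)
        assert sem_pairs == pytest.approx(expected, abs=1e-12)
        assert sem_pooled != pytest.approx(sem_pairs, abs=1e-6)


class TestRMANOVA:
    def test_matches_brute_force(self):
        msr, msc, mse = brute_force_mean_squares(MATRIX_4x3)
        f_expected = msc / mse
        p_expected = stats.f.sf(f_expected, 2, 6)
        f_obs, p = rm_anova(MATRIX_4x3)
        assert f_obs == pytest.approx(f_expected, abs=1e-9)
        assert p == pytest.approx(p_expected, abs=1e-12)

    def test_perfect_learning_infinite_f(self):
        m = np.array([[10.0, 12.0, 14.0], [20.0, 22.0, 24.0], [5.0, 7.0, 9.0]])
        f_obs, p = rm_anova(m)
        assert np.isinf(f_obs) and p == 0.0

    def test_single_trial_rejected(self):
        with pytest.raises(LaserTraceError):
            rm_anova(MATRIX_4x3[:, :1])

    def test_shares_decomposition_with_icc(self):
        ms = mean_squares(MATRIX_4x3)
        f_obs, _ = rm_anova(MATRIX_4x3)
        assert f_obs == ms.msc / ms.mse


class TestSpearman:
    def test_perfect_monotone_decreasing(self):
        rho, _ = speed_accuracy_correlation([90, 80, 70, 60, 50], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(-1.0)

    def test_hand_rank_oracle(self):
        # ranks of (5,4,3,1,2) against (1..5): covariance by hand gives -0.9
        rho, _ = speed_accuracy_correlation([1, 2, 3, 4, 5], [5, 4, 3, 1, 2])
        assert rho == pytest.approx(-0.9, abs=1e-12)

    def test_simulated_trade_off_detected(self):
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(50):
            speed = rng.uniform(30, 90, 50)
            acuity = 100 - 0.5 * speed + rng.normal(0, 5, 50)
            rho, p = speed_accuracy_correlation(acuity, speed)
            hits += (rho < 0) and (p < 0.05)
        assert hits >= 48

    def test_degenerate_inputs(self):
        with pytest.raises(LaserTraceError):
            speed_accuracy_correlation([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        with pytest.raises(LaserTraceError):
            speed_accuracy_correlation([1, 2, 3], [3, 2, 1])


class TestCompareGroups:
    def test_identical_paired_vectors(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_groups(a, a, paired=True)
        assert res.t == 0.0 and res.mean_diff == 0.0
        assert res.ci_low == 0.0 and res.ci_high == 0.0

    def test_constant_shift_zero_variance_flagged(self):
        a = np.array([1.0, 2.0, 3.0])
        res = compare_groups(a + 2.0, a, paired=True)
        assert res.degenerate and np.isinf(res.t) and res.mean_diff == 2.0

    def test_paired_matches_textbook_formula(self):
        a = np.array([71.0, 68.0, 75.0, 80.0, 66.0])
        b = np.array([65.0, 70.0, 72.0, 74.0, 60.0])
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_manual = 2 * stats.t.sf(abs(t_manual), len(d) - 1)
        res = compare_groups(a, b, paired=True)
        assert res.t == pytest.approx(t_manual, abs=1e-12)
        assert res.p == pytest.approx(p_manual, abs=1e-12)

    def test_independent_welch_matches_formula(self):
        a = np.array([71.0, 68.0, 75.0, 80.0, 66.0, 73.0])
        b = np.array([65.0, 70.0, 72.0, 74.0])
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_manual = (a.mean() - b.mean()) / np.sqrt(va + vb)
        res = compare_groups(a, b, paired=False)
        assert res.t == pytest.approx(t_manual, abs=1e-12)

    def test_size_violations(self):
        with pytest.raises(LaserTraceError):
            compare_groups([1.0], [1.0, 2.0])
        with pytest.raises(LaserTraceError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)


class TestNormalityGate:
    def test_type_i_rate_near_alpha(self):
        rng = np.random.default_rng(5)
        rejections = sum(normality_gate(rng.normal(size=50))[1] < 0.05
                         for _ in range(300))
        assert 0.02 <= rejections / 300 <= 0.09

    def test_skewed_sample_rejected_often(self):
        rng = np.random.default_rng(6)
        rejections = sum(normality_gate(rng.exponential(size=50))[1] < 0.05
                         for _ in range(100))
        assert rejections / 100 > 0.5

    def test_domain_errors(self):
        with pytest.raises(LaserTraceError):
            normality_gate([1.0, 2.0])
        with pytest.raises(LaserTraceError):
            normality_gate(np.ones(10))


def test_holm_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.stats.multitest")
    p = np.array([0.01, 0.04, 0.03, 0.005, 0.2])
    np.testing.assert_allclose(holm_adjust(p),
                               sm.multipletests(p, method="holm")[1], atol=1e-12)


class TestModelResults:
    def test_fit_and_summary(self):
        rng = np.random.default_rng(8)
        m = rng.normal(70, 10, (20, 1)) + rng.normal(0, 5, (20, 3))
        res = TrialReliability(m, condition="right/dorsal").fit()
        assert res.n_subjects == 20 and res.k_trials == 3
        assert res.icc_consistency_ci[0] <= res.icc_consistency <= res.icc_consistency_ci[1]
        assert res.sem > 0
        text = res.summary()
        assert "right/dorsal" in text and "ICC" in text and "SEM" in text
        d = res.to_dict()
        assert d["n_subjects"] == 20 and len(d["trial_means"]) == 3

    def test_from_dataframe_listwise_deletion(self):
        rows = []
        for s in range(6):
            for t in range(1, 4):
                if s == 0 and t == 2:
                    continue  # one missing trial
                rows.append({"participant": f"P{s}", "trial": t,
                             "acuity_pct": 70.0 + s + t,
                             "hand": "right", "anatomical_direction": "dorsal"})
        df = pd.DataFrame(rows)
        model = TrialReliability.from_dataframe(
            df, where={"hand": "right", "anatomical_direction": "dorsal"})
        assert model.matrix.shape == (5, 3)
        assert model.n_dropped == 1

    def test_reliability_by_condition_groups(self):
        rng = np.random.default_rng(9)
        rows = []
        for s in range(8):
            for hand in ("left", "right"):
                for direction in ("palmar", "dorsal"):
                    for t in range(1, 4):
                        rows.append({"participant": f"P{s}", "hand": hand,
                                     "anatomical_direction": direction, "trial": t,
                                     "acuity_pct": rng.normal(70, 8)})
        out = reliability_by_condition(pd.DataFrame(rows))
        assert set(out) == {"left/palmar", "left/dorsal", "right/palmar", "right/dorsal"}
        for res in out.values():
            assert res.n_subjects == 8
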