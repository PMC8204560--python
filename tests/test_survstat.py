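"""Kernel-level checks against hand values and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from omsurv import survstat as ss
from omsurv.errors import UndefinedResultError, UnfitError, ValidationError

# ---------------------------------------------------------------------------
# Kaplan-Meier


class TestKM:
    def test_hand_product_limit(self):
        km = ss.km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert np.allclose(km.event_times, [1.0, 3.0])
        assert np.allclose(km.survival, [2 / 3, 0.0])
        assert km.survival_at(0.5) == 1.0
        assert km.survival_at(2.5) == pytest.approx(2 / 3)

    def test_all_censored_is_flat_one(self):
        km = ss.km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_single_event_drops_to_zero(self):
        km = ss.km_estimate([5.0], [1])
        assert km.survival_at(5.0) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            ss.km_estimate([-1.0, 2.0], [1, 1])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0, 100, allow_nan=False), st.integers(0, 1)),
            min_size=1,
            max_size=40,
        )
    )
    def test_curve_monotone_in_unit_interval(self, samples):
        time = [t for t, _ in samples]
        event = [e for _, e in samples]
        km = ss.km_estimate(time, event)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((km.survival >= 0) & (km.survival <= 1))
        assert np.all(np.diff(km.at_risk.astype(float)) <= 0)


# ---------------------------------------------------------------------------
# Log-rank


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 0, 1, 1, 0, 1]
        r = ss.logrank_test(t, e, [0, 0, 0, 1, 1, 1])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_oe_over_v_oracle(self, small_surv):
        time, event, group = small_surv
        r = ss.logrank_test(time, event, group)
        assert r.statistic == pytest.approx(
            oracles.logrank_2group_oracle(time, event, group), abs=1e-10
        )

    def test_three_groups_df(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1, 30)
        e = np.ones(30, int)
        r = ss.logrank_test(t, e, np.arange(30) % 3)
        assert r.df == 2

    def test_label_permutation_invariance(self, small_surv):
        time, event, group = small_surv
        a = ss.logrank_test(time, event, group)
        b = ss.logrank_test(time, event, np.where(group == 0, "B", "A"))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_no_events_gives_null_result(self):
        r = ss.logrank_test([1.0, 2.0], [0, 0], [0, 1])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_matches_lifelines(self, small_surv):
        lifelines = pytest.importorskip("lifelines")
        time, event, group = small_surv
        ours = ss.logrank_test(time, event, group)
        ref = lifelines.statistics.logrank_test(
            time[group == 0], time[group == 1], event[group == 0], event[group == 1]
        )
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-8)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-8)


# ---------------------------------------------------------------------------
# Cox fitting


class TestCox:
    def test_beta_matches_grid_search_oracle(self):
        # untied times so the simple-oracle partial likelihood is exact
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        fit = ss.cox_fit(x[:, None], time, event)
        oracle = oracles.cox_grid_search_oracle(x, time, event)
        assert fit.coef[0] == pytest.approx(oracle, abs=1e-3)

    def test_matches_lifelines_with_ties(self, small_surv):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        time, event, group = small_surv
        fit = ss.cox_fit(group[:, None].astype(float), time, event)
        cph = lifelines.CoxPHFitter()
        cph.fit(pd.DataFrame({"t": time, "e": event, "x": group}), "t", "e")
        # lifelines' own convergence criterion is looser than ours (our fit
        # has gradient ~1e-16 and a slightly higher partial likelihood)
        assert fit.coef[0] == pytest.approx(cph.params_.iloc[0], abs=5e-4)
        assert fit.se[0] == pytest.approx(cph.standard_errors_.iloc[0], abs=5e-4)

    def test_constant_covariate_is_uninformative(self):
        fit = ss.cox_fit(np.zeros((5, 1)), [1, 2, 3, 4, 5], [1, 1, 0, 1, 1])
        assert fit.coef[0] == 0.0
        assert fit.p_values[0] == 1.0

    def test_no_events_raises(self):
        with pytest.raises(UnfitError):
            ss.cox_fit(np.ones((3, 1)), [1, 2, 3], [0, 0, 0])

    def test_full_shrinkage_at_large_penalty(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        t = rng.exponential(1, 40)
        e = np.ones(40, int)
        fit = ss.cox_fit(X, t, e, l1_penalty=10.0)
        assert np.all(fit.coef == 0.0)

    def test_likelihood_is_local_max(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 2))
        t = rng.exponential(np.exp(-0.5 * X[:, 0]))
        e = (rng.uniform(size=50) < 0.8).astype(int)
        fit = ss.cox_fit(X, t, e)
        ll_hat, _, _ = ss._efron_ll(X, t, e, fit.coef, order=0)
        ll_zero, _, _ = ss._efron_ll(X, t, e, np.zeros(2), order=0)
        assert ll_hat >= ll_zero
        for j in range(2):
            for d in (-1e-3, 1e-3):
                pert = fit.coef.copy()
                pert[j] += d
                ll_p, _, _ = ss._efron_ll(X, t, e, pert, order=0)
                assert ll_hat >= ll_p - 1e-12


class TestLassoPath:
    @pytest.fixture()
    def fixture_data(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((80, 4))
        t = rng.exponential(np.exp(-(X[:, 0] - 0.7 * X[:, 1])))
        e = np.ones(80, int)
        return X, t, e

    def test_all_zero_at_lambda_max(self, fixture_data):
        X, t, e = fixture_data
        lmax = ss.lambda_max(X, t, e)
        fit = ss.cox_fit(X, t, e, l1_penalty=lmax * 1.0001)
        assert np.all(fit.coef == 0.0)

    def test_path_end_matches_unpenalized(self, fixture_data):
        X, t, e = fixture_data
        lams, coefs = ss.lasso_path(X, t, e, n_lambdas=30, eps=1e-4)
        ref = ss.cox_fit(X, t, e).coef
        assert np.allclose(coefs[-1], ref, atol=1e-3)

    def test_path_shape_and_active_set_growth(self, fixture_data):
        X, t, e = fixture_data
        lams, coefs = ss.lasso_path(X, t, e, n_lambdas=20)
        assert coefs.shape == (20, 4)
        assert (coefs[-1] != 0).sum() >= (coefs[0] != 0).sum()

    def test_increasing_sequence_rejected(self, fixture_data):
        X, t, e = fixture_data
        with pytest.raises(Exception):
            ss.lasso_path(X, t, e, lambdas=np.array([0.1, 0.2]))


# ---------------------------------------------------------------------------
# Breslow baseline


class TestBreslow:
    def test_zero_beta_equals_nelson_aalen(self, small_surv):
        time, event, _ = small_surv
        X = np.random.default_rng(0).standard_normal((len(time), 2))
        bh = ss.breslow_baseline(np.zeros(2), X, time, event)
        na_t, na_h = ss.nelson_aalen(time, event)
        assert np.allclose(bh.times, na_t)
        assert np.allclose(bh.cumhaz, na_h)

    def test_hand_summation(self, small_surv):
        time, event, group = small_surv
        beta = np.array([0.4])
        bh = ss.breslow_baseline(beta, group[:, None].astype(float), time, event)
        oracle = oracles.breslow_oracle(beta, group[:, None].astype(float), time, event)
        for t, h in oracle.items():
            assert bh.at(t) == pytest.approx(h, abs=1e-10)

    def test_single_event_increment(self):
        x = np.array([[0.0], [1.0], [2.0]])
        beta = np.array([0.3])
        bh = ss.breslow_baseline(beta, x, [1.0, 2.0, 3.0], [1, 0, 0])
        assert bh.cumhaz[0] == pytest.approx(1.0 / np.exp(beta[0] * x[:, 0]).sum())


# ---------------------------------------------------------------------------
# Concordance


class TestCIndex:
    def test_perfect_ranking(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert ss.concordance_index(-t, t, np.ones(4, int)) == 1.0

    def test_matches_brute_force_pairs(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 30).round(1)  # rounding creates ties
        e = (rng.uniform(size=30) < 0.7).astype(int)
        s = rng.standard_normal(30).round(1)
        assert ss.concordance_index(s, t, e) == oracles.cindex_oracle(s, t, e)

    def test_negation_antisymmetry(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(1, 25)
        e = (rng.uniform(size=25) < 0.7).astype(int)
        s = rng.standard_normal(25)  # continuous: no ties
        c = ss.concordance_index(s, t, e)
        assert ss.concordance_index(-s, t, e) == pytest.approx(1 - c, abs=1e-12)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(UndefinedResultError):
            ss.concordance_index([1.0, 2.0], [1.0, 2.0], [0, 0])


# ---------------------------------------------------------------------------
# tdROC


class TestTdRoc:
    def test_reduces_to_binary_roc_without_censoring(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(1, 60)
        e = np.ones(60, int)
        s = -t + rng.normal(0, 0.5, 60)
        horizon = float(np.median(t))
        roc = ss.td_roc(s, t, e, horizon)
        assert roc.auc == pytest.approx(oracles.binary_auc_oracle(s, t <= horizon), abs=1e-10)

    def test_perfect_separation(self):
        t = np.array([1.0, 2.0, 8.0, 9.0])
        e = np.ones(4, int)
        s = np.array([10.0, 9.0, 1.0, 0.0])
        assert ss.td_roc(s, t, e, 5.0).auc == 1.0

    def test_endpoints_and_trapezoid(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(1, 40)
        e = (rng.uniform(size=40) < 0.8).astype(int)
        roc = ss.td_roc(rng.standard_normal(40), t, e, float(np.median(t)))
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert roc.auc == pytest.approx(np.trapezoid(roc.tpr, roc.fpr))

    def test_null_scores_near_half(self):
        aucs = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            n = 2000
            t = rng.exponential(10, n)
            c = rng.exponential(30, n)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            s = rng.standard_normal(n)  # independent of outcome
            aucs.append(ss.td_roc(s, time, event, 10.0).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_no_cases_raises(self):
        with pytest.raises(UndefinedResultError):
            ss.td_roc([1.0, 2.0], [5.0, 6.0], [1, 1], 1.0)


# ---------------------------------------------------------------------------
# Calibration


class TestCalibration:
    def test_equal_frequency_binning(self):
        pairs = ss.calibration_curve(
            [0.1, 0.4, 0.6, 0.9], [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], 2.5, n_bins=2
        )
        assert len(pairs) == 2

    def test_identical_predictions_single_bin(self):
        pairs = ss.calibration_curve(
            [0.5] * 6, np.arange(1.0, 7.0), [1] * 6, 3.0, n_bins=3
        )
        assert len(pairs) == 1

    def test_well_calibrated_model(self):
        # predictions drawn from the generating exponential model
        rng = np.random.default_rng(9)
        n = 4000
        rate = rng.uniform(0.05, 0.4, n)
        t = rng.exponential(1 / rate)
        pred = np.exp(-rate * 5.0)  # true S(5) per sample
        pairs = ss.calibration_curve(pred, t, np.ones(n, int), 5.0, n_bins=5)
        err = [abs(p - o) for p, o in pairs if np.isfinite(o)]
        assert np.mean(err) < 0.05
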