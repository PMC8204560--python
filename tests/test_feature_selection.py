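"""Screening operators and the sequential chaining engine."""

import numpy as np
import pandas as pd
import pytest

from omsurv import feature_selection as fs, survstat
from omsurv.errors import ParameterError, ValidationError
from omsurv.tabular_io import OmicsClinicalTable


def table_from_matrix(X, time, event, prefix="f"):
    feats = pd.DataFrame(X, columns=[f"{prefix}{j}" for j in range(X.shape[1])])
    feats.index = [f"s{i}" for i in range(len(feats))]
    return OmicsClinicalTable(
        features=feats,
        time=pd.Series(np.asarray(time, float), index=feats.index),
        event=pd.Series(np.asarray(event, int), index=feats.index),
    )


@pytest.fixture()
def random_table():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((60, 6))
    t = rng.exponential(np.exp(-X[:, 0]))
    e = (rng.uniform(size=60) < 0.8).astype(int)
    return table_from_matrix(X, t, e)


class TestCorrelationFilter:
    def test_identical_features_keep_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        tab = table_from_matrix(np.column_stack([x, x]), np.arange(1.0, 31), np.ones(30))
        step = fs.correlation_filter(tab, 0.7)
        assert step.n_out == 1

    def test_uncorrelated_identity(self, random_table):
        step = fs.correlation_filter(random_table, 0.99)
        assert step.survivors == random_table.feature_ids

    def test_postcondition_no_surviving_pair_above_threshold(self):
        # structured 5-feature fixture with strong cross-correlations
        rng = np.random.default_rng(2)
        z = rng.standard_normal(100)
        X = np.column_stack(
            [
                z,
                z + 0.1 * rng.standard_normal(100),
                -z + 0.1 * rng.standard_normal(100),
                rng.standard_normal(100),
                2 * z + 0.05 * rng.standard_normal(100),
            ]
        )
        tab = table_from_matrix(X, np.arange(1.0, 101), np.ones(100))
        step = fs.correlation_filter(tab, 0.7)
        kept = [tab.feature_ids.index(f) for f in step.survivors]
        R = np.corrcoef(X, rowvar=False)
        for a in kept:
            for b in kept:
                if a != b:
                    assert abs(R[a, b]) <= 0.7
        # and the removed features each record their retained partner
        removed = set(tab.feature_ids) - set(step.survivors)
        for f in removed:
            assert step.statistics.loc[f, "removed_for"] in step.survivors

    def test_threshold_validation(self, random_table):
        with pytest.raises(ParameterError):
            fs.correlation_filter(random_table, 1.5)


class TestUnivariateCox:
    def test_planted_features_recovered(self, planted_table):
        hits = []
        for seed in range(5):
            table, truth = planted_table(seed=seed, n_null=195)
            step = fs.univariate_cox_screen(table, 0.05)
            hits.append(len(set(step.survivors) & set(truth.prognostic_ids)))
        assert all(h >= 4 for h in hits)

    def test_type_one_error_within_binomial_bounds(self, planted_table):
        # 500 pure-null features at alpha = 0.05: expect ~25 +- 2.58 sd hits
        table, _ = planted_table(seed=42, n_null=495, beta=0.0)
        step = fs.univariate_cox_screen(table, 0.05)
        n_false = len(step.survivors)
        lo = 500 * 0.05 - 2.576 * np.sqrt(500 * 0.05 * 0.95)
        hi = 500 * 0.05 + 2.576 * np.sqrt(500 * 0.05 * 0.95)
        assert lo <= n_false <= hi

    def test_alpha_near_one_keeps_everything(self, random_table):
        step = fs.univariate_cox_screen(random_table, 0.999999)
        assert step.survivors == random_table.feature_ids


class TestLogrankScreen:
    def test_constant_feature_dropped_with_warning(self, random_table):
        X = random_table.features.copy()
        X["flat"] = 1.0
        tab = random_table.with_features(X)
        step = fs.logrank_screen(tab, 0.05)
        assert "flat" not in step.survivors
        assert any("flat" in w for w in step.warnings)

    def test_strong_effect_detected(self, planted_table):
        table, truth = planted_table(seed=3)
        step = fs.logrank_screen(table, 0.05)
        p_planted = step.statistics.loc[truth.prognostic_ids, "p"]
        assert (p_planted < 1e-3).sum() >= 3

    def test_composition_identity_with_manual_logrank(self, random_table):
        step = fs.logrank_screen(random_table, 0.05)
        for feat in random_table.feature_ids:
            x = random_table.features[feat].to_numpy()
            hi = (x > np.median(x)).astype(int)
            ref = survstat.logrank_test(
                random_table.time.to_numpy(), random_table.event.to_numpy(), hi
            )
            assert step.statistics.loc[feat, "p"] == pytest.approx(ref.p_value)


class TestMultivariateCox:
    def test_noise_feature_removed(self):
        kept_signal, kept_noise = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 300
            X = rng.standard_normal((n, 2))
            t = rng.exponential(np.exp(-X[:, 0]))  # only feature 0 matters
            c = rng.exponential(np.quantile(t, 0.9), n)
            time, event = np.minimum(t, c), (t <= c).astype(int)
            tab = table_from_matrix(X, time, event)
            step = fs.multivariate_cox_screen(tab, 0.05)
            kept_signal += "f0" in step.survivors
            kept_noise += "f1" in step.survivors
        assert kept_signal >= 18
        assert kept_noise <= 2  # noise removed in >= 90% of datasets

    def test_single_feature_equals_univariate(self, random_table):
        tab = random_table.subset_features(["f0"])
        multi = fs.multivariate_cox_screen(tab, 0.05)
        uni = fs.univariate_cox_screen(tab, 0.05)
        assert multi.survivors == uni.survivors

    def test_more_features_than_events_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 8))
        tab = table_from_matrix(X, np.arange(1.0, 11), [1, 0, 0, 0, 0, 1, 0, 0, 1, 0])
        with pytest.raises(ValidationError, match="single-factor"):
            fs.multivariate_cox_screen(tab, 0.05)

    def test_collinear_design_named(self, random_table):
        X = random_table.features.copy()
        X["dup"] = X["f0"] * 2.0
        tab = random_table.with_features(X)
        with pytest.raises(survstat.CollinearityError):
            fs.multivariate_cox_screen(tab, 0.05)


class TestLassoScreen:
    def test_fixed_lambda_above_max_selects_nothing(self, random_table):
        lmax = survstat.lambda_max(
            random_table.features.to_numpy(),
            random_table.time.to_numpy(),
            random_table.event.to_numpy(),
        )
        step = fs.lasso_screen(random_table, "fixed", fixed_lambda=lmax * 2)
        assert step.n_out == 0

    def test_planted_recovery_cv_min(self, planted_table):
        hits = []
        for seed in range(5):
            table, truth = planted_table(seed=100 + seed, n_null=45, n_samples=250)
            step = fs.lasso_screen(table, "cv_min", seed=seed)
            hits.append(len(set(step.survivors) & set(truth.prognostic_ids)))
        assert all(h >= 3 for h in hits)

    def test_larger_fixed_lambda_selects_subset(self, planted_table):
        # monotone shrinkage checked on fixed penalties (no CV noise)
        table, _ = planted_table(seed=7, n_null=25, n_samples=150)
        lmax = survstat.lambda_max(
            table.features.to_numpy(), table.time.to_numpy(), table.event.to_numpy()
        )
        small = fs.lasso_screen(table, "fixed", fixed_lambda=lmax * 0.05)
        large = fs.lasso_screen(table, "fixed", fixed_lambda=lmax * 0.3)
        assert set(large.survivors) <= set(small.survivors)

    def test_deterministic_per_seed(self, planted_table):
        table, _ = planted_table(seed=9, n_null=15, n_samples=120)
        a = fs.lasso_screen(table, "cv_min", seed=5)
        b = fs.lasso_screen(table, "cv_min", seed=5)
        assert a.survivors == b.survivors
        assert a.params == b.params


class TestChain:
    def test_sizes_monotone_and_subsets(self, planted_table):
        table, _ = planted_table(seed=1, n_null=45, n_samples=250)
        trace = fs.run_selection_chain(
            table, [{"method": "uni_cox", "alpha": 0.05}, {"method": "lasso", "seed": 0}]
        )
        sizes = [s.n_in for s in trace.steps] + [trace.steps[-1].n_out]
        assert sizes == sorted(sizes, reverse=True)
        assert set(trace.steps[1].input_features) == set(trace.steps[0].survivors)
        assert set(trace.final_features) <= set(trace.steps[0].survivors)

    def test_singleton_chain_equals_operator(self, random_table):
        trace = fs.run_selection_chain(random_table, [{"method": "uni_cox", "alpha": 0.2}])
        direct = fs.univariate_cox_screen(random_table, 0.2)
        assert trace.final_features == direct.survivors

    def test_paired_combinations_expressible(self, planted_table):
        # the single-factor + Lasso pairings are all 2-step chains
        table, _ = planted_table(seed=2, n_null=25, n_samples=150)
        for first in (
            {"method": "correlation", "r_threshold": 0.7},
            {"method": "uni_cox", "alpha": 0.05},
            {"method": "logrank", "alpha": 0.05},
        ):
            trace = fs.run_selection_chain(table, [first, {"method": "lasso", "seed": 0}])
            assert len(trace.steps) <= 2

    def test_empty_result_stops_chain(self, random_table):
        trace = fs.run_selection_chain(
            table=random_table,
            steps=[{"method": "uni_cox", "alpha": 1e-12}, {"method": "lasso"}],
        )
        assert trace.status == "empty_result"
        assert len(trace.steps) == 1
        assert trace.final_features == []

    def test_trace_export_covers_every_feature(self, random_table):
        trace = fs.run_selection_chain(random_table, [{"method": "uni_cox", "alpha": 0.2}])
        frame = trace.to_frame()
        assert set(frame["feature"]) == set(random_table.feature_ids)
        assert {"kept", "p"} <= set(frame.columns)
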