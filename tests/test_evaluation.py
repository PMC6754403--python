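"""Fidelity metrics: z-scores, KS calibration tests, masked correlations,
weighted R^2, distinguishability AUC, scaled RMSE, covariance diagnostics,
the ADAS-Cog11 composite, and progressor effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from trajgen import CohortTable, evaluation, synthetic
from trajgen.evaluation import (BaselineForecaster, adascog11_total,
                                bonferroni_flags, cohens_d,
                                covariance_diagnostics, distinguishability_auc,
                                ks_normal_test, masked_correlations,
                                scaled_rmse, weighted_r2, z_scores)
from trajgen.schema import ADASCOG11_COMPONENTS, default_schema
from trajgen.simulation import TrajectorySet


def _moments_frame(cells):
    return pd.DataFrame(cells, columns=["patient_id", "visit_month", "variable",
                                        "mean", "var", "n"])


class TestZScores:
    def test_observed_equal_to_mean_gives_zero(self, reference_model):
        params, enc = reference_model
        df = pd.DataFrame([("p1", 3, "y0", 2.0)],
                          columns=["patient_id", "visit_month", "variable", "value"])
        cohort = CohortTable(df, enc.schema, validate=False)
        mom = _moments_frame([("p1", 3, "y0", 2.0, 4.0, 10)])
        zs = z_scores(cohort, mom)
        assert zs["z"].iloc[0] == pytest.approx(0.0)

    def test_two_sd_above_mean_gives_two(self, reference_model):
        params, enc = reference_model
        df = pd.DataFrame([("p1", 3, "y0", 5.0)],
                          columns=["patient_id", "visit_month", "variable", "value"])
        cohort = CohortTable(df, enc.schema, validate=False)
        mom = _moments_frame([("p1", 3, "y0", 1.0, 4.0, 10)])
        assert z_scores(cohort, mom)["z"].iloc[0] == pytest.approx(2.0)

    def test_zero_variance_cells_excluded(self, reference_model):
        params, enc = reference_model
        df = pd.DataFrame([("p1", 3, "y0", 5.0), ("p1", 3, "y1", 1.0)],
                          columns=["patient_id", "visit_month", "variable", "value"])
        cohort = CohortTable(df, enc.schema, validate=False)
        mom = _moments_frame([("p1", 3, "y0", 1.0, 0.0, 10),
                              ("p1", 3, "y1", 1.0, 1.0, 10)])
        zs = z_scores(cohort, mom)
        assert len(zs) == 1
        assert zs.attrs["excluded"] == 1


class TestKSNormal:
    def test_standard_normal_sample_statistics_give_zero(self):
        # construct a sample with exactly mean 0, sd 1
        z = np.array([-1.0, 1.0, -1.0, 1.0]) * np.sqrt(3.0) / 2.0
        d, p = ks_normal_test(z)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_shifted_mean_half(self):
        """mu=0.5, sigma=1: supremum at the midpoint, Phi(.25)-Phi(-.25)."""
        rng = np.random.default_rng(0)
        z = rng.standard_normal(4000)
        z = (z - z.mean()) / z.std(ddof=1) + 0.5
        d, _ = ks_normal_test(z)
        assert d == pytest.approx(stats.norm.cdf(0.25) - stats.norm.cdf(-0.25),
                                  abs=1e-6)
        assert d == pytest.approx(0.1974, abs=1e-4)

    def test_doubled_sd(self):
        """mu=0, sigma=2: grid supremum matches an independent optimizer."""
        rng = np.random.default_rng(1)
        z = rng.standard_normal(4000)
        z = (z - z.mean()) / z.std(ddof=1) * 2.0
        d, _ = ks_normal_test(z)
        opt = optimize.minimize_scalar(
            lambda x: -abs(stats.norm.cdf(x, scale=2.0) - stats.norm.cdf(x)),
            bounds=(0.1, 5.0), method="bounded")
        assert d == pytest.approx(-opt.fun, abs=1e-6)
        assert d == pytest.approx(0.161, abs=1e-3)

    def test_p_value_from_kolmogorov_distribution(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(500)
        z = (z - z.mean()) / z.std(ddof=1) + 0.3
        d, p = ks_normal_test(z)
        from scipy.special import kolmogorov
        assert p == pytest.approx(kolmogorov(np.sqrt(500) * d), rel=1e-12)


class TestBonferroni:
    def test_single_test_flagged(self):
        assert bonferroni_flags([0.04]).tolist() == [True]

    def test_family_correction(self):
        flags = bonferroni_flags([0.04] + [1.0] * 9)
        assert flags.tolist() == [False] + [False] * 9  # threshold 0.005

    def test_all_ones_unflagged(self):
        assert not bonferroni_flags([1.0] * 7).any()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_flags([])


class TestMaskedCorrelations:
    @staticmethod
    def _cohort(values: dict, schema):
        rows = [(p, m, v, x) for (p, m, v), x in values.items()]
        return CohortTable(pd.DataFrame(
            rows, columns=["patient_id", "visit_month", "variable", "value"]),
            schema, validate=False)

    def test_lagged_self_correlation_of_persistent_variable(self, reference_model):
        _, enc = reference_model
        values = {}
        for i in range(20):
            for m in (0, 3):
                values[(f"p{i}", m, "y0")] = float(i)  # constant in time
                values[(f"p{i}", m, "y1")] = float(i % 5)
        cohort = self._cohort(values, enc.schema)
        tab = masked_correlations(cohort, lag_months=3,
                                  variables=["y0", "y1"])
        self_corr = tab[(tab.var_a == "y0") & (tab.var_b == "y0")
                        & (tab.visit_month == 0)]["corr"].iloc[0]
        assert self_corr == pytest.approx(1.0)

    def test_independent_variables_near_zero(self, reference_model):
        _, enc = reference_model
        rng = np.random.default_rng(3)
        n = 4000
        values = {}
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        for i in range(n):
            values[(f"p{i:04d}", 0, "y0")] = a[i]
            values[(f"p{i:04d}", 0, "y1")] = b[i]
        cohort = self._cohort(values, enc.schema)
        tab = masked_correlations(cohort, 0, variables=["y0", "y1"])
        r = tab[tab.visit_month == 0]["corr"].iloc[0]
        assert abs(r) < 3 / np.sqrt(n)

    def test_presence_fraction_one_when_complete(self, reference_model):
        _, enc = reference_model
        values = {(f"p{i}", 0, v): float(np.sin(i + hash(v) % 7))
                  for i in range(10) for v in ("y0", "y1")}
        cohort = self._cohort(values, enc.schema)
        tab = masked_correlations(cohort, 0, variables=["y0", "y1"])
        assert tab[tab.visit_month == 0]["presence"].iloc[0] == 1.0

    def test_too_few_complete_pairs_unavailable(self, reference_model):
        _, enc = reference_model
        values = {("p0", 0, "y0"): 1.0, ("p0", 0, "y1"): 2.0,
                  ("p1", 0, "y0"): 3.0, ("p1", 0, "y1"): 1.0,
                  ("p2", 0, "y0"): 2.0}
        cohort = self._cohort(values, enc.schema)
        tab = masked_correlations(cohort, 0, variables=["y0", "y1"])
        row = tab[tab.visit_month == 0].iloc[0]
        assert np.isnan(row["corr"])
        assert row["presence"] == pytest.approx(2 / 3)


class TestWeightedR2:
    def test_perfect_agreement(self):
        x = np.array([0.1, -0.2, 0.5, 0.3])
        assert weighted_r2(x, x, np.array([1.0, 2.0, 0.5, 1.0])) == \
            pytest.approx(1.0)

    def test_constant_model_gives_zero(self):
        x = np.array([0.1, -0.2, 0.5, 0.3])
        y = np.full(4, 0.2)
        assert weighted_r2(x, y, np.ones(4)) == 0.0

    def test_hand_built_four_point_example_matches_normal_equations(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.1, 0.8, 2.3, 2.7])
        w = np.array([1.0, 0.5, 2.0, 1.0])
        # independent weighted normal-equations solve
        Wm = np.diag(w)
        A = np.column_stack([np.ones(4), x])
        beta = np.linalg.solve(A.T @ Wm @ A, A.T @ Wm @ y)
        resid = y - A @ beta
        ybar = (w * y).sum() / w.sum()
        expected = 1 - (w * resid ** 2).sum() / (w * (y - ybar) ** 2).sum()
        assert weighted_r2(x, y, w) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.01, 100))
    def test_invariant_to_weight_rescaling(self, scale):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.1, 0.8, 2.3, 2.7])
        w = np.array([1.0, 0.5, 2.0, 1.0])
        assert weighted_r2(x, y, w * scale) == pytest.approx(
            weighted_r2(x, y, w), rel=1e-9)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_r2(np.ones(3), np.ones(3), np.zeros(3))


def _paired_sets(n=60, shift=0.0, missing=False, seed=0):
    """A cohort and a 'synthetic' trajectory set copied (or shifted) from it."""
    _, enc = synthetic.reference_crbm(seed=1)
    rng = np.random.default_rng(seed)
    rows, srows = [], []
    for i in range(n):
        pid = f"p{i:03d}"
        for v in ("y0", "y1", "y2"):
            x = rng.standard_normal()
            if not (missing and rng.random() < 0.3):
                rows.append((pid, 3, v, x))
            srows.append((pid, 0, 3, v, x + shift, False))
    cohort = CohortTable(pd.DataFrame(
        rows, columns=["patient_id", "visit_month", "variable", "value"]),
        enc.schema, validate=False)
    sdf = pd.DataFrame(srows, columns=["patient_id", "replicate", "visit_month",
                                       "variable", "value", "post_dropout"])
    return cohort, TrajectorySet(sdf, "type_i", seed)


class TestDistinguishabilityAUC:
    def test_identical_data_indistinguishable(self):
        cohort, trajs = _paired_sets()
        mean, sd, aucs = distinguishability_auc(cohort, trajs, 3, n_repeats=5,
                                                seed=1, variables=["y0", "y1", "y2"])
        assert abs(mean - 0.5) < 0.1

    def test_large_shift_perfectly_separable(self):
        cohort, trajs = _paired_sets(shift=10.0)
        mean, _, _ = distinguishability_auc(cohort, trajs, 3, n_repeats=3,
                                            seed=2, variables=["y0", "y1", "y2"])
        assert mean > 0.95

    def test_imputed_cells_copied_into_synthetic(self):
        """With heavy missingness and identical underlying values the copy
        rule keeps AUC near 1/2; without it missingness would leak class."""
        cohort, trajs = _paired_sets(missing=True, seed=3)
        mean, _, _ = distinguishability_auc(cohort, trajs, 3, n_repeats=5,
                                            seed=3, variables=["y0", "y1", "y2"])
        assert abs(mean - 0.5) < 0.12

    def test_empty_visit_rejected(self):
        cohort, trajs = _paired_sets()
        with pytest.raises(ValueError):
            distinguishability_auc(cohort, trajs, 18, n_repeats=2, seed=0,
                                   variables=["y0", "y1", "y2"])


class TestScaledRMSE:
    def test_perfect_predictions(self):
        o = np.array([1.0, 2.0, 3.0])
        assert scaled_rmse(o, o) == 0.0

    def test_mean_prediction_is_exactly_one(self):
        o = np.array([1.0, 2.0, 3.0, 4.0])
        p = np.full(4, o.mean())
        assert scaled_rmse(p, o) == pytest.approx(1.0, rel=1e-12)

    def test_homogeneous_in_errors(self):
        rng = np.random.default_rng(4)
        o = rng.standard_normal(50)
        p1 = o + 0.3
        p2 = o + 0.6
        assert scaled_rmse(p2, o) == pytest.approx(2 * scaled_rmse(p1, o))

    def test_missing_observations_excluded(self):
        o = np.array([1.0, np.nan, 3.0])
        p = np.array([1.0, 99.0, 3.0])
        assert scaled_rmse(p, o) == 0.0

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            scaled_rmse(np.array([1.0, 1.0]), np.array([2.0, 2.0]))


class TestBaselineForecaster:
    @staticmethod
    def _cohort(n=30, seed=0):
        schema = default_schema()
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            pid = f"p{i:03d}"
            rows.append((pid, 0, "age", float(rng.normal(73, 8))))
            rows.append((pid, 0, "adas_word_recall", float(rng.integers(0, 10))))
            rows.append((pid, 12, "adas_word_recall", float(rng.integers(0, 10))))
        return CohortTable(pd.DataFrame(
            rows, columns=["patient_id", "visit_month", "variable", "value"]),
            schema, validate=False)

    def test_constant_target_predicted_exactly(self):
        cohort = self._cohort()
        df = cohort.df.copy()
        df.loc[df["visit_month"] == 12, "value"] = 7.0
        const = CohortTable(df, cohort.schema, validate=False)
        fc = BaselineForecaster(seed=0).fit(const, ("adas_word_recall", 12))
        preds = fc.predict(const)
        assert np.allclose(preds.to_numpy(float), 7.0)

    def test_deterministic_given_seed(self):
        cohort = self._cohort()
        p1 = BaselineForecaster(seed=5).fit(cohort, ("adas_word_recall", 12)) \
            .predict(cohort)
        p2 = BaselineForecaster(seed=5).fit(cohort, ("adas_word_recall", 12)) \
            .predict(cohort)
        assert p1.equals(p2)

    def test_linear_learner_recovers_linear_map(self):
        schema = default_schema()
        rng = np.random.default_rng(6)
        rows = []
        for i in range(80):
            pid = f"p{i:03d}"
            age = float(rng.normal(73, 8))
            rows.append((pid, 0, "age", age))
            rows.append((pid, 12, "weight", 10.0 + 0.5 * age))
        cohort = CohortTable(pd.DataFrame(
            rows, columns=["patient_id", "visit_month", "variable", "value"]),
            schema, validate=False)
        fc = BaselineForecaster(learner="linear").fit(cohort, ("weight", 12))
        target = cohort.wide(12, ["weight"])["weight"].astype(float)
        assert np.allclose(fc.predict(cohort).to_numpy(), target, atol=1e-6)


class TestCovarianceDiagnostics:
    def test_identical_covariances_slope_one(self):
        rng = np.random.default_rng(7)
        X = rng.multivariate_normal(np.zeros(4), np.eye(4) + 0.5, size=3000)
        out = covariance_diagnostics(X, X.copy())
        assert out["model_slope"] == pytest.approx(1.0, abs=1e-9)

    def test_theil_sen_robust_to_gross_outlier(self):
        x = np.linspace(1, 10, 10)
        y = 2 * x
        y[3] = 50.0
        res = stats.theilslopes(y, x)
        assert res.slope == pytest.approx(2.0, abs=1e-9)

    def test_conditional_mean_predictor_underproduces_covariance(self):
        """Two-level Gaussian generator: the deterministic conditional-mean
        predictions miss exactly the expected-conditional-covariance term."""
        rng = np.random.default_rng(8)
        d = 3
        A = rng.normal(0, 0.5, (d, d))
        Sc = np.eye(d) * 0.7
        n = 60000
        x0 = rng.standard_normal((n, d))
        xt = x0 @ A.T + rng.multivariate_normal(np.zeros(d), Sc, size=n)
        mean_pred = x0 @ A.T
        out = covariance_diagnostics(xt, xt.copy(), mean_pred,
                                     include_diagonal=True)
        deficit = out["data_cov"] - out["comparator_cov"]
        iu = np.triu_indices(d, 0)
        assert np.allclose(deficit, Sc[iu], atol=0.05)


class TestADASCog11:
    def test_all_zero_components_sum_to_zero(self):
        comps = {name: 0.0 for name in ADASCOG11_COMPONENTS}
        assert adascog11_total(comps) == 0.0

    def test_arithmetic_sum(self):
        comps = {name: float(i + 1)
                 for i, name in enumerate(ADASCOG11_COMPONENTS)}
        assert adascog11_total(comps) == 66.0

    def test_delayed_word_recall_excluded(self):
        comps = {name: 1.0 for name in ADASCOG11_COMPONENTS}
        total = adascog11_total(comps)
        comps["adas_delayed_word_recall"] = 99.0
        assert adascog11_total(comps) == total == 11.0

    def test_missing_component_makes_total_missing(self):
        comps = {name: 1.0 for name in ADASCOG11_COMPONENTS[:-1]}
        assert np.isnan(adascog11_total(comps))


class TestEffectSizes:
    def test_identical_groups_give_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert cohens_d(a, a.copy()) == 0.0

    def test_unit_separation_with_unit_sd(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 20000)
        b = rng.normal(1, 1, 20000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.03)

    def test_worked_pooled_sd_example(self):
        a = np.array([0.0, 0.0, 1.0, 1.0])
        b = np.array([1.0, 1.0, 2.0, 2.0])
        assert cohens_d(a, b) == pytest.approx(1.0 / np.sqrt(1 / 3), rel=1e-12)
        assert cohens_d(a, b) == pytest.approx(1.7320508, abs=1e-6)

    def test_zero_pooled_sd_reported_unavailable(self):
        assert np.isnan(cohens_d(np.ones(3), np.ones(4)))
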