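"""Goodness-of-fit and forecasting evaluation battery.

The battery judges a generative trajectory model on four axes:

* **Per-patient calibration** — z-scores standardize each observed value by
  the model's per-patient conditional mean and standard deviation; pooled
  across patients they should be mean 0, sd 1 if the conditional moments
  are right. A Kolmogorov-Smirnov statistic between the fitted normal
  N(mu_hat, sigma_hat) and the standard normal, with p-values from the
  asymptotic Kolmogorov distribution at sqrt(n) D and a Bonferroni
  correction over all (variable, visit) cells, flags miscalibrated cells.
* **Correlation recovery** — equal-time and lagged Pearson correlations,
  computed on complete pairs only and compared between observed and
  simulated data by a weighted least-squares R^2 (weights = fraction of
  complete pairs).
* **Distinguishability** — a logistic regression trained (5-fold CV) to
  separate real records from baseline-matched synthetic records; AUC 0.5
  means indistinguishable. Mean-imputed real cells are copied into the
  paired synthetic records so missingness itself carries no signal.
* **Forecasting** — sd-scaled RMSE of the model's conditional-mean forecast
  against per-target supervised baselines, covariance diagnostics via the
  law of total variance and Theil-Sen slopes, the ADAS-Cog11 composite, and
  Cohen's d effect sizes separating fast from slow progressors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler

from .cohort import CohortTable
from .schema import ADASCOG11_COMPONENTS, VISIT_MONTHS
from .simulation import TrajectorySet

__all__ = [
    "z_scores", "ks_normal_test", "bonferroni_flags", "zscore_report",
    "masked_correlations", "weighted_r2", "distinguishability_auc",
    "scaled_rmse", "BaselineForecaster", "covariance_diagnostics",
    "adascog11_total", "adascog11_series", "cohens_d",
    "progressor_effect_sizes", "FidelityReport",
]


# ---------------------------------------------------------------------------
# z-score calibration
# ---------------------------------------------------------------------------

def z_scores(observed: CohortTable, moments: pd.DataFrame,
             min_var: float = 1e-12) -> pd.DataFrame:
    """Standardize observations by per-patient conditional moments.

    ``moments`` is the frame produced by ``simulation.conditional_moments``
    (columns patient_id, visit_month, variable, mean, var). Cells with
    conditional variance below ``min_var`` are excluded (degenerate
    z-scores) and reported in the ``excluded`` attribute of the result.
    Returns a frame with columns patient_id, visit_month, variable, z.
    """
    obs = observed.df[observed.df["visit_month"] > 0]
    obs = obs[obs["variable"].isin(set(moments["variable"]))].copy()
    obs["value"] = pd.to_numeric(obs["value"])
    merged = obs.merge(moments, on=["patient_id", "visit_month", "variable"],
                       how="inner")
    degenerate = merged["var"] < min_var
    ok = merged[~degenerate].copy()
    ok["z"] = (ok["value"] - ok["mean"]) / np.sqrt(ok["var"])
    out = ok[["patient_id", "visit_month", "variable", "z"]].reset_index(drop=True)
    out.attrs["excluded"] = int(degenerate.sum())
    return out


def ks_normal_test(z: np.ndarray) -> tuple[float, float]:
    """Kolmogorov-Smirnov distance of the fitted normal from N(0, 1).

    The sample mean and sd of the z-values parameterize a normal
    N(mu_hat, sigma_hat); the statistic is sup_x |Phi(x; mu_hat, sigma_hat)
    - Phi(x; 0, 1)| (dense-grid supremum), and the p-value comes from the
    asymptotic Kolmogorov distribution evaluated at sqrt(n) D.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n < 2:
        raise ValueError("need at least two z-values")
    mu, sd = float(np.mean(z)), float(np.std(z, ddof=1))
    if sd <= 0:
        raise ValueError("degenerate z sample (zero standard deviation)")
    lo = min(-10.0, mu - 10.0 * sd)
    hi = max(10.0, mu + 10.0 * sd)
    grid = np.linspace(lo, hi, 200001)
    d = float(np.max(np.abs(stats.norm.cdf(grid, loc=mu, scale=sd)
                            - stats.norm.cdf(grid))))
    p = float(special.kolmogorov(np.sqrt(n) * d))
    return d, p


def bonferroni_flags(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Familywise significance flags: p < alpha / m over the whole family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    return p < alpha / p.size


def zscore_report(observed: CohortTable, moments: pd.DataFrame,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Per (variable, visit) z-moments, KS tests, and Bonferroni flags."""
    zs = z_scores(observed, moments)
    rows = []
    for (var, month), grp in zs.groupby(["variable", "visit_month"]):
        if len(grp) < 2 or np.std(grp["z"].to_numpy(), ddof=1) <= 0:
            continue
        d, p = ks_normal_test(grp["z"].to_numpy())
        rows.append({"variable": var, "visit_month": month, "n": len(grp),
                     "z_mean": float(grp["z"].mean()),
                     "z_sd": float(grp["z"].std(ddof=1)),
                     "ks_stat": d, "p_value": p})
    report = pd.DataFrame(rows)
    if len(report):
        report["significant"] = bonferroni_flags(report["p_value"].to_numpy(), alpha)
    return report


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def _wide_units(data: CohortTable | TrajectorySet, visit: int,
                variables: list[str]) -> pd.DataFrame:
    """Rows = sample units (patients, or patient x replicate for simulations)."""
    if isinstance(data, CohortTable):
        return data.wide(visit, variables).apply(pd.to_numeric, errors="coerce")
    df = data.df[(data.df["visit_month"] == visit)
                 & data.df["variable"].isin(variables)]
    out = df.pivot_table(index=["patient_id", "replicate"], columns="variable",
                         values="value", aggfunc="first")
    return out.reindex(columns=variables).apply(pd.to_numeric, errors="coerce")


def _masked_corr_pair(a: np.ndarray, b: np.ndarray,
                      min_pairs: int = 3) -> tuple[float, float]:
    both = np.isfinite(a) & np.isfinite(b)
    frac = float(both.mean()) if a.size else 0.0
    if both.sum() < min_pairs:
        return np.nan, frac
    x, y = a[both], b[both]
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, frac
    return float(np.corrcoef(x, y)[0, 1]), frac


def masked_correlations(data: CohortTable | TrajectorySet,
                        lag_months: int = 0,
                        variables: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlations over complete pairs only.

    For ``lag_months`` 0, correlations are computed per visit between every
    pair of dynamic variables. For lags 3 or 6, variable a at visit t is
    correlated with variable b at visit t + lag for every valid t. The
    presence fraction (complete pairs / sample units) accompanies each
    value; pairs with fewer than 3 complete observations are NaN.
    """
    if lag_months not in (0, 3, 6):
        raise ValueError("lag_months must be 0, 3 or 6")
    schema = data.schema if isinstance(data, CohortTable) else None
    if variables is None:
        if schema is None:
            raise ValueError("variables must be given for trajectory sets")
        variables = [v for v in schema.dynamic if v != "dropout"]
    rows = []
    for t_from in VISIT_MONTHS:
        t_to = t_from + lag_months
        if t_to not in VISIT_MONTHS:
            continue
        A = _wide_units(data, t_from, variables)
        B = A if lag_months == 0 else _wide_units(data, t_to, variables)
        if lag_months != 0:
            B = B.reindex(A.index)
        An, Bn = A.to_numpy(dtype=float), B.to_numpy(dtype=float)
        for i, va in enumerate(variables):
            j_start = i + 1 if lag_months == 0 else 0
            for j in range(j_start, len(variables)):
                r, frac = _masked_corr_pair(An[:, i], Bn[:, j])
                rows.append({"visit_month": t_from, "lag_months": lag_months,
                             "var_a": va, "var_b": variables[j],
                             "corr": r, "presence": frac})
    return pd.DataFrame(rows)


def weighted_r2(observed_corrs: np.ndarray, model_corrs: np.ndarray,
                weights: np.ndarray) -> float:
    """R^2 of a weighted least-squares fit of model vs observed correlations.

    Weights are the fraction of data present when each correlation was
    computed; the value is invariant to rescaling all weights.
    """
    x = np.asarray(observed_corrs, dtype=float)
    y = np.asarray(model_corrs, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(w)
    x, y, w = x[keep], y[keep], w[keep]
    if w.sum() <= 0:
        raise ValueError("all-zero weights")
    W = w / w.sum()
    xb, yb = W @ x, W @ y
    sxx = W @ (x - xb) ** 2
    sxy = W @ ((x - xb) * (y - yb))
    syy = W @ (y - yb) ** 2
    if syy == 0:
        return 0.0
    if sxx == 0:
        return 0.0
    beta = sxy / sxx
    ss_res = syy - beta * sxy
    return float(1.0 - ss_res / syy)


# ---------------------------------------------------------------------------
# Distinguishability AUC
# ---------------------------------------------------------------------------

def distinguishability_auc(real: CohortTable, synthetic: TrajectorySet,
                           visit: int, n_repeats: int = 100, seed: int = 0,
                           variables: list[str] | None = None,
                           n_folds: int = 5) -> tuple[float, float, np.ndarray]:
    """AUC of a logistic regression separating real from synthetic records.

    Each repeat draws one synthetic replicate per patient, mean-imputes the
    real records' missing cells, copies those imputed values into the same
    cells of the paired synthetic record (so missingness carries no class
    signal), and scores a linear-log-odds classifier by pooled out-of-fold
    predictions under 5-fold CV grouped by patient (a patient's real and
    synthetic records share a fold, so memorized training rows cannot leak
    into the test fold). Returns (mean, sd, per-repeat AUCs).
    """
    if variables is None:
        variables = [v for v in real.schema.dynamic if v != "dropout"]
    real_wide = real.wide(visit, variables).apply(pd.to_numeric, errors="coerce")
    patients = [p for p in real_wide.index
                if np.isfinite(real_wide.loc[p].to_numpy(dtype=float)).any()]
    if not patients:
        raise ValueError(f"no observed patients at visit {visit}")
    real_wide = real_wide.loc[patients]
    X_real = real_wide.to_numpy(dtype=float)
    col_means = np.nanmean(X_real, axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    miss = ~np.isfinite(X_real)
    X_real_imp = np.where(miss, col_means[None, :], X_real)

    sdf = synthetic.df[(synthetic.df["visit_month"] == visit)
                       & synthetic.df["variable"].isin(variables)]
    synth_cube = sdf.pivot_table(index=["patient_id", "replicate"],
                                 columns="variable", values="value",
                                 aggfunc="first").reindex(columns=variables)
    n_reps = synthetic.n_replicates
    rng = np.random.default_rng(seed)
    aucs = []
    y = np.concatenate([np.ones(len(patients)), np.zeros(len(patients))])
    for _ in range(n_repeats):
        reps = rng.integers(0, n_reps, size=len(patients))
        X_syn = np.stack([
            synth_cube.loc[(p, r)].to_numpy(dtype=float)
            for p, r in zip(patients, reps)])
        X_syn = np.where(miss, col_means[None, :], X_syn)
        X = np.concatenate([X_real_imp, X_syn])
        X = StandardScaler().fit_transform(X)
        groups = np.tile(np.arange(len(patients)), 2)
        cv = GroupKFold(n_splits=n_folds, shuffle=True,
                        random_state=int(rng.integers(2 ** 31)))
        scores = np.zeros(len(y))
        for tr, te in cv.split(X, y, groups):
            clf = LogisticRegression(max_iter=1000)
            clf.fit(X[tr], y[tr])
            scores[te] = clf.decision_function(X[te])
        aucs.append(roc_auc_score(y, scores))
    aucs = np.asarray(aucs)
    return float(aucs.mean()), float(aucs.std(ddof=1)), aucs


# ---------------------------------------------------------------------------
# Forecast errors
# ---------------------------------------------------------------------------

def scaled_rmse(predictions: np.ndarray, observations: np.ndarray) -> float:
    """RMSE scaled by the (population) sd of the observations.

    1.0 corresponds to predicting the mean; samples with missing
    observations are excluded.
    """
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    keep = np.isfinite(o) & np.isfinite(p)
    p, o = p[keep], o[keep]
    if o.size == 0:
        raise ValueError("no complete prediction/observation pairs")
    sd = float(np.std(o))
    if sd == 0:
        raise ValueError("zero observation sd; scaled error undefined")
    return float(np.sqrt(np.mean((p - o) ** 2)) / sd)


class BaselineForecaster:
    """Per-target supervised comparator trained on baseline covariates.

    A pluggable learner (tree ensemble by default, linear optional) maps
    mean-imputed baseline features to one (variable, visit) target. Serves
    only as the comparison arm in scaled-RMSE tables.
    """

    def __init__(self, learner: str = "forest", n_estimators: int = 200,
                 seed: int = 0):
        if learner not in ("forest", "linear"):
            raise ValueError("learner must be 'forest' or 'linear'")
        self.learner = learner
        self.n_estimators = n_estimators
        self.seed = seed
        self._model = None
        self._feature_names: list[str] = []
        self._feature_means: np.ndarray | None = None

    def _features(self, cohort: CohortTable) -> pd.DataFrame:
        schema = cohort.schema
        wide = cohort.wide(0)
        frames = {}
        for name in schema.names:
            vs = schema[name]
            col = wide[name] if name in wide.columns else pd.Series(index=wide.index,
                                                                    dtype=float)
            if vs.value_type == "categorical":
                for lv in vs.levels:
                    frames[f"{name}={lv}"] = (col == lv).astype(float).where(col.notna())
            else:
                frames[name] = pd.to_numeric(col, errors="coerce")
        return pd.DataFrame(frames, index=wide.index)

    def fit(self, train: CohortTable, target: tuple[str, int]) -> "BaselineForecaster":
        variable, visit = target
        feats = self._features(train)
        y = pd.to_numeric(train.wide(visit, [variable])[variable], errors="coerce")
        keep = y.notna()
        if keep.sum() == 0:
            raise ValueError(f"no training rows with observed target {target}")
        X = feats.loc[keep].to_numpy(dtype=float)
        self._feature_names = list(feats.columns)
        finite = np.isfinite(X)
        counts = finite.sum(axis=0)
        self._feature_means = np.where(
            counts > 0, np.where(finite, X, 0.0).sum(axis=0) / np.maximum(counts, 1),
            0.0)
        X = np.where(np.isfinite(X), X, self._feature_means[None, :])
        if self.learner == "forest":
            self._model = RandomForestRegressor(n_estimators=self.n_estimators,
                                                random_state=self.seed)
        else:
            self._model = LinearRegression()
        self._model.fit(X, y[keep].to_numpy(dtype=float))
        return self

    def predict(self, cohort: CohortTable) -> pd.Series:
        if self._model is None:
            raise RuntimeError("fit must be called first")
        feats = self._features(cohort)[self._feature_names]
        X = feats.to_numpy(dtype=float)
        X = np.where(np.isfinite(X), X, self._feature_means[None, :])
        return pd.Series(self._model.predict(X), index=feats.index)


# ---------------------------------------------------------------------------
# Covariance diagnostics (law of total variance)
# ---------------------------------------------------------------------------

def _pairwise_covariances(X: np.ndarray, include_diagonal: bool = False) -> np.ndarray:
    C = np.cov(X, rowvar=False, ddof=1)
    iu = np.triu_indices(C.shape[0], 0 if include_diagonal else 1)
    return C[iu]


def covariance_diagnostics(data: np.ndarray, model_samples: np.ndarray,
                           comparator_predictions: np.ndarray | None = None,
                           include_diagonal: bool = False) -> dict:
    """Pairwise covariances and Theil-Sen slopes of model/comparator vs data.

    Stochastic model samples carry both terms of the law of total variance
    (covariance of conditional means plus expected conditional covariance);
    deterministic conditional-mean predictions carry only the first, so
    their covariances systematically undershoot. The Theil-Sen estimator
    (median of pairwise slopes) makes the comparison robust to the few very
    large covariance pairs.
    """
    out = {"data_cov": _pairwise_covariances(data, include_diagonal),
           "model_cov": _pairwise_covariances(model_samples, include_diagonal)}
    res = stats.theilslopes(out["model_cov"], out["data_cov"])
    out["model_slope"] = float(res.slope)
    if comparator_predictions is not None:
        out["comparator_cov"] = _pairwise_covariances(comparator_predictions,
                                                      include_diagonal)
        res = stats.theilslopes(out["comparator_cov"], out["data_cov"])
        out["comparator_slope"] = float(res.slope)
    return out


# ---------------------------------------------------------------------------
# ADAS-Cog composite and progressor profiling
# ---------------------------------------------------------------------------

def adascog11_total(components: dict[str, float] | pd.Series) -> float:
    """Sum of the 11 ADAS-Cog components (delayed word recall excluded).

    Returns NaN when any constituent component is missing.
    """
    vals = []
    for name in ADASCOG11_COMPONENTS:
        v = components.get(name) if isinstance(components, dict) else \
            (components[name] if name in components.index else None)
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            return float("nan")
        vals.append(float(v))
    return float(sum(vals))


def adascog11_series(wide: pd.DataFrame) -> pd.Series:
    """Row-wise ADAS-Cog11 totals of a patients x variables frame."""
    missing_cols = [c for c in ADASCOG11_COMPONENTS if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"missing ADAS components: {missing_cols}")
    sub = wide[list(ADASCOG11_COMPONENTS)].apply(pd.to_numeric, errors="coerce")
    total = sub.sum(axis=1)
    total[sub.isna().any(axis=1)] = np.nan
    return total


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute standardized mean difference with the pooled sample sd.

    Pooling uses (n-1)-weighted sample variances: s_p^2 =
    ((n_a - 1) s_a^2 + (n_b - 1) s_b^2) / (n_a + n_b - 2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two values")
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        return float("nan")
    return float(abs(a.mean() - b.mean()) / np.sqrt(sp2))


def progressor_effect_sizes(trajectories: TrajectorySet,
                            baseline_variables: list[str],
                            horizon_month: int = 18,
                            tail_fraction: float = 0.05) -> pd.DataFrame:
    """Baseline effect sizes separating fast from slow progressors.

    Synthetic patients are ranked by their change in ADAS-Cog11 total from
    baseline to ``horizon_month``; the top and bottom ``tail_fraction``
    are the fast and slow progressors. For each baseline variable the
    absolute Cohen's d between the two groups is reported (NaN when the
    pooled sd vanishes).
    """
    df = trajectories.df
    units = df.pivot_table(index=["patient_id", "replicate"], columns="variable",
                           values="value", aggfunc="first")
    base = df[df["visit_month"] == 0].pivot_table(
        index=["patient_id", "replicate"], columns="variable", values="value",
        aggfunc="first")
    end = df[df["visit_month"] == horizon_month].pivot_table(
        index=["patient_id", "replicate"], columns="variable", values="value",
        aggfunc="first")
    change = (adascog11_series(end) - adascog11_series(base)).dropna()
    n = len(change)
    if n < 40:
        raise ValueError("need at least 40 synthetic patients for 5% tails")
    k = max(1, int(round(tail_fraction * n)))
    ranked = change.sort_values()
    slow_idx, fast_idx = ranked.index[:k], ranked.index[-k:]
    rows = []
    for var in baseline_variables:
        if var not in base.columns:
            continue
        vals = pd.to_numeric(base[var], errors="coerce")
        a = vals.reindex(fast_idx).dropna().to_numpy()
        b = vals.reindex(slow_idx).dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            d = float("nan")
        else:
            d = cohens_d(a, b)
        rows.append({"variable": var, "abs_cohens_d": d,
                     "n_fast": len(a), "n_slow": len(b)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclass
class FidelityReport:
    """Structured results of the evaluation battery."""
    zscore_table: pd.DataFrame | None = None
    correlation_r2: dict = field(default_factory=dict)
    auc_by_visit: pd.DataFrame | None = None
    scaled_rmse_table: pd.DataFrame | None = None
    covariance_slopes: dict = field(default_factory=dict)
    effect_sizes: pd.DataFrame | None = None

    def to_json(self, path: str) -> None:
        doc = {}
        for name in ("zscore_table", "auc_by_visit", "scaled_rmse_table",
                     "effect_sizes"):
            frame = getattr(self, name)
            doc[name] = None if frame is None else frame.to_dict(orient="records")
        doc["correlation_r2"] = self.correlation_r2
        doc["covariance_slopes"] = self.covariance_slopes
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, default=float)
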