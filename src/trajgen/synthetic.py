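"""Synthetic cohort generation.

Two generators live here. :func:`generate_cohort` draws a cohort with the
qualitative structure of an MCI/AD clinical-trial population from a latent
Gaussian copula: variables within a category (ADAS, MMSE, laboratory,
clinical, background) share a strong latent correlation, categories are only
weakly coupled, cognitive variables drift over visits (a "progressor"
subpopulation drifts faster, widening the right tail of the ADAS-Cog total),
patients drop out with a per-visit hazard after which all dynamic values are
missing, and per-variable missingness is injected at schema-declared rates.
Marginals are matched to the schema's baseline statistics: lognormal moment
matching for positive continuous variables, exact frequencies for binary and
categorical ones, and a discretized-normal fit for ordinal components.

:func:`reference_crbm` builds a small, fully specified model (with its
schema and identity encoder) that serves as ground truth for calibration
tests, and :func:`generate_from_reference_model` draws a cohort from any
such model so that evaluation metrics have known ideal values (z-scores
standard normal, distinguishability AUC one half).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import crbm, simulation
from .cohort import CohortTable
from .crbm import CRBMParams, VisibleLayout
from .encoding import Encoder
from .schema import SchemaSet, VariableSchema, VISIT_MONTHS, default_schema


class GeneratorConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Configuration of the copula cohort generator.

    ``within_category_corr`` must exceed ``between_category_corr``: category
    blocks of clinical variables correlate strongly internally but only
    weakly across categories. ``progression_drift`` is the per-visit mean
    increment of the cognitive variables on the latent (probit) scale; the
    ``progressor_fraction`` of patients drift ``progressor_accel`` times
    faster. ``dropout_hazard`` is a per-visit absorbing dropout probability.
    """
    n_patients: int = 200
    seed: int = 0
    schema: SchemaSet = field(default_factory=default_schema)
    within_category_corr: float = 0.4
    between_category_corr: float = 0.05
    progression_drift: float = 0.12
    progressor_fraction: float = 0.2
    progressor_accel: float = 3.0
    temporal_corr: float = 0.7
    dropout_hazard: float = 0.05
    missingness: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.between_category_corr < self.within_category_corr < 1:
            raise GeneratorConfigError(
                "need 0 <= between_category_corr < within_category_corr < 1")
        for name in ("progressor_fraction", "dropout_hazard", "temporal_corr"):
            if not 0 <= getattr(self, name) <= 1:
                raise GeneratorConfigError(f"{name} must lie in [0, 1]")
        if self.n_patients < 0:
            raise GeneratorConfigError("n_patients must be >= 0")

    def missing_rate(self, name: str) -> float:
        if self.missingness is not None and name in self.missingness:
            return self.missingness[name]
        return self.schema[name].missing_rate


# ---------------------------------------------------------------------------
# Marginal transforms
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) matching a lognormal's mean and sd exactly."""
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def fit_ordinal_pmf(lo: int, hi: int, mean: float, sd: float) -> np.ndarray:
    """Probabilities on {lo..hi} matching (mean, sd) via a discretized normal.

    A normal N(loc, scale) is integrated over unit bins (tails folded into
    the end bins) and (loc, scale) are solved so the discrete moments hit
    the targets. Falls back to the best least-squares fit when the exact
    moments are infeasible on the support.
    """
    levels = np.arange(lo, hi + 1, dtype=float)
    edges = np.concatenate([[-np.inf], levels[:-1] + 0.5, [np.inf]])

    def pmf(loc: float, log_scale: float) -> np.ndarray:
        cdf = stats.norm.cdf(edges, loc=loc, scale=np.exp(log_scale))
        p = np.diff(cdf)
        return p / p.sum()

    def resid(x: np.ndarray) -> np.ndarray:
        p = pmf(*x)
        m = p @ levels
        s = np.sqrt(max(p @ (levels - m) ** 2, 1e-12))
        return np.array([m - mean, s - sd])

    sol = optimize.least_squares(resid, x0=np.array([mean, np.log(max(sd, 0.05))]),
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return pmf(*sol.x)


def _category_correlation(schema: SchemaSet, rho_in: float,
                          rho_out: float) -> np.ndarray:
    names = schema.names
    cats = np.array([schema[n].category for n in names])
    C = np.full((len(names), len(names)), rho_out)
    same = cats[:, None] == cats[None, :]
    C[same] = rho_in
    np.fill_diagonal(C, 1.0)
    if np.linalg.eigvalsh(C).min() <= 1e-10:
        raise GeneratorConfigError("block correlation matrix is not positive definite")
    return C


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a schema-conforming cohort from the latent Gaussian copula."""
    schema = config.schema
    names = schema.names
    rng = np.random.default_rng(config.seed)
    C = _category_correlation(schema, config.within_category_corr,
                              config.between_category_corr)
    L = np.linalg.cholesky(C)
    n, d, T = config.n_patients, len(names), len(VISIT_MONTHS)

    # latent AR(1) process with copula-correlated innovations
    phi = config.temporal_corr
    g = np.empty((T, n, d))
    g[0] = rng.standard_normal((n, d)) @ L.T
    for t in range(1, T):
        innov = rng.standard_normal((n, d)) @ L.T
        g[t] = phi * g[t - 1] + np.sqrt(1.0 - phi ** 2) * innov

    # progressor subpopulation and per-variable latent drift
    progressor = rng.random(n) < config.progressor_fraction
    accel = np.where(progressor, config.progressor_accel, 1.0)
    drift_sign = np.array([{"ADAS": 1.0, "MMSE": -1.0}.get(schema[v].category, 0.0)
                           for v in names])

    # absorbing dropout: sampled per visit, all later dynamic values missing
    dropped_at = np.full(n, T + 1)
    if "dropout" in names and config.dropout_hazard > 0:
        events = rng.random((n, T)) < config.dropout_hazard
        events[:, 0] = False
        any_event = events.any(axis=1)
        dropped_at[any_event] = events[any_event].argmax(axis=1)

    ordinal_pmf = {v: fit_ordinal_pmf(int(schema[v].bounds[0]), int(schema[v].bounds[1]),
                                      schema[v].baseline_mean, schema[v].baseline_sd)
                   for v in names if schema[v].value_type == "ordinal"}

    rows: list[tuple] = []
    pids = np.array([f"p{i:05d}" for i in range(n)])
    miss_draw = rng.random((T, n, d))
    for j, name in enumerate(names):
        vs = schema[name]
        visits = (0,) if vs.temporal == "static" else range(T)
        rate = config.missing_rate(name)
        for t in visits:
            z = g[t, :, j] + drift_sign[j] * config.progression_drift * t * accel
            if name == "dropout":
                vals = (dropped_at == t).astype(float)
            elif vs.value_type == "continuous":
                mu, s = _lognormal_params(vs.baseline_mean, vs.baseline_sd)
                vals = np.exp(mu + s * z)
            elif vs.value_type == "binary":
                vals = (stats.norm.cdf(z) < vs.baseline_mean).astype(float)
            elif vs.value_type == "ordinal":
                pmf = ordinal_pmf[name]
                u = stats.norm.cdf(z)
                vals = float(vs.bounds[0]) + np.searchsorted(
                    np.cumsum(pmf)[:-1], u, side="right").astype(float)
            else:  # categorical
                probs = np.asarray(vs.level_probs, dtype=float)
                probs = probs / probs.sum()
                u = stats.norm.cdf(z)
                idx = np.searchsorted(np.cumsum(probs)[:-1], u, side="right")
                vals = np.array([vs.levels[i] for i in idx], dtype=object)
            observed = miss_draw[t, :, j] >= rate
            if vs.temporal == "dynamic":
                observed &= t <= dropped_at
            for i in np.nonzero(observed)[0]:
                rows.append((pids[i], VISIT_MONTHS[t], name, vals[i]))
    df = pd.DataFrame(rows, columns=["patient_id", "visit_month", "variable", "value"])
    return CohortTable(df, schema, validate=False)


# ---------------------------------------------------------------------------
# Reference models (known ground truth)
# ---------------------------------------------------------------------------

def reference_schema(n_dynamic: int = 5, n_static_continuous: int = 1,
                     n_static_binary: int = 1) -> SchemaSet:
    """Small all-numeric schema for reference-model studies (synthetic)."""
    variables = [VariableSchema(f"y{i}", "clinical", "continuous", "dynamic")
                 for i in range(n_dynamic)]
    variables += [VariableSchema(f"s{i}", "background", "continuous", "static")
                  for i in range(n_static_continuous)]
    variables += [VariableSchema(f"b{i}", "background", "binary", "static")
                  for i in range(n_static_binary)]
    return SchemaSet(variables)


def reference_crbm(n_dynamic: int = 5, n_static_continuous: int = 1,
                   n_static_binary: int = 1, n_hidden: int = 3, seed: int = 0,
                   coupling: float = 0.6) -> tuple[CRBMParams, Encoder]:
    """A fully specified small model with continuous dynamic units.

    Weights are drawn randomly and rescaled to a fixed spectral norm
    (``coupling`` < 1 keeps the h-integrated Gaussian visible layer proper),
    so conditional trajectories are correlated but sampling stays stable.
    Returns the parameters and a matching identity-transform encoder.
    """
    schema = reference_schema(n_dynamic, n_static_continuous, n_static_binary)
    encoder = Encoder(schema).set_identity_stats()
    layout = VisibleLayout.from_columns(
        encoder.columns_for(schema.dynamic), encoder.columns_for(schema.static),
        {v: schema[v].value_type for v in schema.names})
    rng = np.random.default_rng(seed)
    n_vis = layout.n_cols
    W = rng.normal(size=(n_vis, n_hidden))
    W *= coupling / np.linalg.norm(W, 2)
    vis_bias = np.zeros(n_vis)
    b = layout.binary_cols
    vis_bias[b] = rng.normal(0.0, 0.3, size=len(b))
    params = CRBMParams(layout, W, vis_bias, rng.normal(0.0, 0.3, size=n_hidden),
                        np.ones(n_vis), np.ones(n_hidden))
    return params, encoder


def generate_from_reference_model(params: CRBMParams, encoder: Encoder,
                                  n_patients: int, seed: int = 0,
                                  missing_rate: float = 0.0) -> CohortTable:
    """Sample one full trajectory per patient from a known model.

    Because the generating distribution is the model itself, downstream
    fidelity metrics have known ideal values. Optional MCAR missingness can
    be injected to exercise imputation paths.
    """
    trajs = simulation.simulate_de_novo(params, encoder, n_patients, seed=seed)
    if n_patients == 0:
        return CohortTable(pd.DataFrame(
            columns=["patient_id", "visit_month", "variable", "value"]),
            encoder.schema, validate=False)
    df = trajs.df[["patient_id", "visit_month", "variable", "value"]]
    if missing_rate > 0:
        rng = np.random.default_rng(seed + 1)
        df = df[rng.random(len(df)) >= missing_rate]
    return CohortTable(df, encoder.schema, validate=False)
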