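"""Trajectory simulation from a fitted model.

Two kinds of synthetic trajectories are produced: *type i* trajectories are
conditioned on the observed baselines of real patients (the model iteratively
adds visits, clamping the previous visit and the static covariates); *type
ii* trajectories belong to entirely synthetic patients whose baseline is
itself drawn from the model by long unclamped Gibbs sampling.

Per-patient conditional means and variances at a future visit — the minimum
mean-squared-error forecast and its uncertainty — are Monte-Carlo estimates
over conditional replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import crbm
from .cohort import CohortTable
from .crbm import CRBMParams
from .encoding import Encoder
from .schema import VISIT_MONTHS

#: Gibbs steps used for one conditional draw.
DEFAULT_GIBBS_STEPS = 20
#: Burn-in steps for unclamped (de novo) baseline sampling.
DEFAULT_DENOVO_BURNIN = 500


@dataclass
class TrajectorySet:
    """Simulated trajectories in long format.

    ``df`` columns: patient_id, replicate, visit_month, variable, value,
    post_dropout (True for visits after a sampled dropout event). ``kind``
    tags the provenance: ``"type_i"`` (conditioned on real baselines) or
    ``"type_ii"`` (de novo).
    """
    df: pd.DataFrame
    kind: str
    seed: int
    model_id: str = ""

    @property
    def patients(self) -> list[str]:
        return sorted(self.df["patient_id"].unique())

    @property
    def n_replicates(self) -> int:
        return int(self.df["replicate"].max()) + 1 if len(self.df) else 0

    def wide(self, visit_month: int, variables: list[str],
             replicate: int | None = None) -> pd.DataFrame:
        df = self.df[self.df["visit_month"] == visit_month]
        if replicate is not None:
            df = df[df["replicate"] == replicate]
        out = df.pivot_table(index="patient_id", columns="variable", values="value",
                             aggfunc="first")
        return out.reindex(columns=variables)

    def to_cohort(self, schema, replicate: int = 0,
                  drop_post_dropout: bool = True) -> CohortTable:
        df = self.df[self.df["replicate"] == replicate]
        if drop_post_dropout:
            df = df[~df["post_dropout"]]
        df = df[df["variable"].isin(schema.names)]
        return CohortTable(df[["patient_id", "visit_month", "variable", "value"]],
                           schema, validate=False)

    def write_csv(self, path: str) -> None:
        self.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Internal helpers on encoded slabs
# ---------------------------------------------------------------------------

def _slab_indices(params: CRBMParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lay = params.layout
    t_cols, tm1_cols, st_cols = (lay.slab_cols("t"), lay.slab_cols("tm1"),
                                 lay.slab_cols("static"))
    if len(t_cols) == 0 or len(tm1_cols) != len(t_cols):
        raise ValueError("layout lacks the [t, t-1, static] slab structure")
    return t_cols, tm1_cols, st_cols


def _impute_baseline(params: CRBMParams, dyn0: np.ndarray, dyn0_mask: np.ndarray,
                     static: np.ndarray, static_mask: np.ndarray,
                     gibbs_steps: int, rng: np.random.Generator):
    """Fill missing baseline coordinates once by conditional sampling."""
    t_cols, tm1_cols, st_cols = _slab_indices(params)
    n = dyn0.shape[0]
    v = crbm.sample_bias_only(params, n, rng)
    clamp = np.zeros(v.shape, dtype=bool)
    v[:, tm1_cols] = np.where(dyn0_mask, dyn0, v[:, tm1_cols])
    v[:, st_cols] = np.where(static_mask, static, v[:, st_cols])
    clamp[:, tm1_cols] = dyn0_mask
    clamp[:, st_cols] = static_mask
    if not (dyn0_mask.all() and static_mask.all()):
        v = crbm.gibbs_sample(v, clamp, params, gibbs_steps, rng)
    return v[:, tm1_cols], v[:, st_cols]


def _step_transition(params: CRBMParams, dyn_prev: np.ndarray, static: np.ndarray,
                     gibbs_steps: int, rng: np.random.Generator) -> np.ndarray:
    """One conditional draw of dynamic(t) given dynamic(t-1) and statics."""
    t_cols, tm1_cols, st_cols = _slab_indices(params)
    n = dyn_prev.shape[0]
    v = crbm.sample_bias_only(params, n, rng)
    v[:, tm1_cols] = dyn_prev
    v[:, st_cols] = static
    clamp = np.zeros(v.shape, dtype=bool)
    clamp[:, tm1_cols] = True
    clamp[:, st_cols] = True
    v = crbm.gibbs_sample(v, clamp, params, gibbs_steps, rng)
    return v[:, t_cols]


def _trajectories_to_frame(encoder: Encoder, patient_ids: np.ndarray,
                           replicate_ids: np.ndarray,
                           static_wide: pd.DataFrame | None,
                           dyn_slabs: list[np.ndarray]) -> pd.DataFrame:
    """Decode per-visit encoded slabs into the long trajectory frame."""
    schema = encoder.schema
    dyn_vars = schema.dynamic
    rows = []
    for t, slab in enumerate(dyn_slabs):
        month = VISIT_MONTHS[t]
        decoded = encoder.decode_slab(slab, dyn_vars)
        for var in dyn_vars:
            vals = decoded[var].to_numpy()
            rows.append(pd.DataFrame({
                "patient_id": patient_ids, "replicate": replicate_ids,
                "visit_month": month, "variable": var, "value": vals}))
    if static_wide is not None:
        for var in static_wide.columns:
            rows.append(pd.DataFrame({
                "patient_id": patient_ids, "replicate": replicate_ids,
                "visit_month": 0, "variable": var,
                "value": np.asarray(static_wide[var])}))
    return pd.concat(rows, ignore_index=True)


def _flag_post_dropout(df: pd.DataFrame, schema) -> pd.DataFrame:
    """Mark visits after an absorbing dropout event, if the schema has one."""
    df = df.copy()
    df["post_dropout"] = False
    if "dropout" not in schema.names:
        return df
    dd = df[df["variable"] == "dropout"]
    drop = dd[pd.to_numeric(dd["value"], errors="coerce") >= 0.5]
    if len(drop):
        first = drop.groupby(["patient_id", "replicate"])["visit_month"].min()
        key = pd.MultiIndex.from_frame(df[["patient_id", "replicate"]])
        cutoff = first.reindex(key).to_numpy()
        df["post_dropout"] = np.isfinite(cutoff) & (df["visit_month"].to_numpy() > cutoff)
    return df


# ---------------------------------------------------------------------------
# Public simulation operations
# ---------------------------------------------------------------------------

def simulate_from_baseline(params: CRBMParams, encoder: Encoder,
                           baselines: CohortTable, horizon_visits: int = 6,
                           n_replicates: int = 1, seed: int = 0,
                           gibbs_steps: int = DEFAULT_GIBBS_STEPS) -> TrajectorySet:
    """Type-i trajectories: iteratively add visits beyond real baselines.

    Missing baseline cells are imputed once by conditional sampling and then
    held fixed for every replicate; observed baseline cells are reproduced
    exactly in the output.
    """
    if horizon_visits < 0 or horizon_visits > len(VISIT_MONTHS) - 1:
        raise ValueError(f"horizon_visits must be in [0, {len(VISIT_MONTHS) - 1}]")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    schema = encoder.schema
    dyn_vars, static_vars = schema.dynamic, schema.static

    base_wide = baselines.wide(0, dyn_vars)
    static_wide0 = baselines.wide(0, static_vars)
    patients = list(base_wide.index.astype(str))
    em_d = encoder.encode_slab(base_wide, dyn_vars)
    em_s = encoder.encode_slab(static_wide0, static_vars)
    dyn0, static = _impute_baseline(params, em_d.X, em_d.mask, em_s.X, em_s.mask,
                                    gibbs_steps, rng)

    # expand to replicates
    n = len(patients)
    rep = np.repeat(np.arange(n_replicates), n)
    pid = np.tile(np.array(patients), n_replicates)
    dyn = np.tile(dyn0, (n_replicates, 1))
    st = np.tile(static, (n_replicates, 1))

    slabs = [dyn]
    for _ in range(horizon_visits):
        dyn = _step_transition(params, slabs[-1], st, gibbs_steps, rng)
        slabs.append(dyn)

    static_decoded = encoder.decode_slab(st, static_vars)
    static_decoded.index = range(len(static_decoded))
    df = _trajectories_to_frame(encoder, pid, rep, static_decoded, slabs)

    # restore exact observed baseline values (dynamic and static)
    for wide, month in ((base_wide, 0), (static_wide0, 0)):
        stacked = wide.stack(future_stack=True).dropna()
        if not len(stacked):
            continue
        obs = {(p, var): val for (p, var), val in stacked.items()}
        sel = (df["visit_month"] == month) & df["variable"].isin(
            {v for (_, v) in obs})
        idx = df.index[sel]
        keyed = list(zip(df.loc[idx, "patient_id"], df.loc[idx, "variable"]))
        vals = df.loc[idx, "value"].to_list()
        df.loc[idx, "value"] = [obs.get(k, v) for k, v in zip(keyed, vals)]

    df = _flag_post_dropout(df, schema)
    return TrajectorySet(df, "type_i", seed)


def simulate_de_novo(params: CRBMParams, encoder: Encoder, n_patients: int,
                     seed: int = 0, gibbs_steps: int = DEFAULT_GIBBS_STEPS,
                     burn_in: int = DEFAULT_DENOVO_BURNIN) -> TrajectorySet:
    """Type-ii trajectories for entirely synthetic patients.

    Statics and the baseline dynamic slab are drawn jointly by unclamped
    Gibbs sampling of the full concatenated vector; visits are then added
    iteratively as for type-i simulation.
    """
    rng = np.random.default_rng(seed)
    schema = encoder.schema
    t_cols, tm1_cols, st_cols = _slab_indices(params)
    if n_patients == 0:
        empty = pd.DataFrame(columns=["patient_id", "replicate", "visit_month",
                                      "variable", "value", "post_dropout"])
        return TrajectorySet(empty, "type_ii", seed)
    v = crbm.sample_bias_only(params, n_patients, rng)
    v = crbm.gibbs_sample(v, None, params, burn_in, rng)
    dyn0, st = v[:, tm1_cols], v[:, st_cols]

    pid = np.array([f"synthetic_{i:05d}" for i in range(n_patients)])
    rep = np.zeros(n_patients, dtype=int)
    slabs = [dyn0]
    for _ in range(len(VISIT_MONTHS) - 1):
        slabs.append(_step_transition(params, slabs[-1], st, gibbs_steps, rng))
    static_decoded = encoder.decode_slab(st, schema.static)
    df = _trajectories_to_frame(encoder, pid, rep, static_decoded, slabs)
    df = _flag_post_dropout(df, schema)
    return TrajectorySet(df, "type_ii", seed)


def conditional_moments(params: CRBMParams, encoder: Encoder,
                        baselines: CohortTable, visits: list[int] | None = None,
                        n_replicates: int = 100, seed: int = 0,
                        gibbs_steps: int = DEFAULT_GIBBS_STEPS) -> pd.DataFrame:
    """Monte-Carlo conditional mean and variance per patient/visit/variable.

    The mean is the model's minimum mean-squared-error forecast given the
    baseline; the variance quantifies per-patient forecast uncertainty. Both
    are on canonical (decoded) variable scales. Returns a frame with columns
    patient_id, visit_month, variable, mean, var, n.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    trajs = simulate_from_baseline(params, encoder, baselines,
                                   horizon_visits=len(VISIT_MONTHS) - 1,
                                   n_replicates=n_replicates, seed=seed,
                                   gibbs_steps=gibbs_steps)
    df = trajs.df
    if visits is not None:
        df = df[df["visit_month"].isin(visits)]
    df = df[df["variable"].isin(encoder.schema.dynamic)]
    grouped = df.groupby(["patient_id", "visit_month", "variable"])["value"]
    out = grouped.agg(mean="mean", var=lambda x: float(np.var(x, ddof=1)),
                      n="count").reset_index()
    return out
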