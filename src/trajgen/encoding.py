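"""Encoding of cohort tables into the model's numeric representation.

Categorical variables are one-hot encoded; positive continuous variables are
log-transformed and z-standardized; other continuous and ordinal variables
are z-standardized (ordinals are decoded by rounding and clipping to their
bounds); binary variables pass through as 0/1. Standardization statistics
are frozen from the training split and reused everywhere else.

The training vectors concatenate, per patient and per consecutive visit
pair, the dynamic variables at visit t, the dynamic variables at visit t-1,
and the static baseline covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, CohortValidationError
from .schema import VISIT_MONTHS, SchemaSet


@dataclass(frozen=True)
class ColumnInfo:
    """One encoded column: its source variable, role, and affine transform."""
    variable: str
    role: str            # 'std' | 'logstd' | 'raw' | 'onehot'
    level: str | None = None
    shift: float = 0.0
    scale: float = 1.0


@dataclass
class EncodedMatrix:
    """Numeric matrix with its column map and missingness mask."""
    X: np.ndarray                 # (n, d) float, zero-filled where missing
    mask: np.ndarray              # (n, d) bool, True = observed
    columns: list[ColumnInfo]
    index: list[str] = field(default_factory=list)


@dataclass
class EncodedPanel:
    """Per-visit encoded arrays for a whole cohort."""
    dynamic: np.ndarray           # (P, T, Dd)
    dynamic_mask: np.ndarray      # (P, T, Dd) bool
    static: np.ndarray            # (P, Ds)
    static_mask: np.ndarray       # (P, Ds) bool
    patients: list[str]
    dynamic_columns: list[ColumnInfo]
    static_columns: list[ColumnInfo]


@dataclass
class TimePairs:
    """Stacked training vectors v = [dynamic(t), dynamic(t-1), static]."""
    X: np.ndarray                 # (N, 2*Dd + Ds)
    mask: np.ndarray              # (N, 2*Dd + Ds) bool
    patient_idx: np.ndarray       # (N,) int, into ``patients``
    t_idx: np.ndarray             # (N,) int, the target visit index (1..T-1)
    patients: list[str]


class Encoder:
    """Fits per-variable transforms on a training cohort and applies them.

    ``fit`` must be called (typically on the training split only) before
    ``encode_slab``/``encode_panel``; the fitted statistics are then frozen.
    """

    def __init__(self, schema: SchemaSet):
        self.schema = schema
        self.stats: dict[str, tuple[float, float]] = {}
        self.fitted = False

    # -- fitting ------------------------------------------------------------
    def fit(self, cohort: CohortTable, patients: list[str] | None = None) -> "Encoder":
        df = cohort.df
        if patients is not None:
            df = df[df["patient_id"].isin(set(map(str, patients)))]
        for name in self.schema.names:
            vs = self.schema[name]
            if vs.value_type in ("categorical", "binary"):
                continue
            vals = df.loc[df["variable"] == name, "value"].astype(float).to_numpy()
            if vs.value_type == "continuous" and vs.positive:
                if len(vals) and np.any(vals <= 0):
                    raise CohortValidationError(
                        f"{name}: non-positive value in a log-transformed variable")
                vals = np.log(vals) if len(vals) else vals
            if len(vals) == 0:
                # fall back to schema-declared baseline statistics
                m = vs.baseline_mean if vs.baseline_mean is not None else 0.0
                s = vs.baseline_sd if vs.baseline_sd else 1.0
                if vs.value_type == "continuous" and vs.positive:
                    s2 = np.log1p((s / m) ** 2) if m > 0 else 1.0
                    m, s = (np.log(m) - s2 / 2.0 if m > 0 else 0.0), np.sqrt(s2)
                self.stats[name] = (float(m), float(s))
            else:
                s = float(np.std(vals))
                self.stats[name] = (float(np.mean(vals)), s if s > 0 else 1.0)
        self.fitted = True
        return self

    def set_identity_stats(self) -> "Encoder":
        """Freeze unit transforms (shift 0, scale 1); used by reference models."""
        for name in self.schema.names:
            self.stats[name] = (0.0, 1.0)
        self.fitted = True
        return self

    # -- column maps --------------------------------------------------------
    def columns_for(self, variables: list[str]) -> list[ColumnInfo]:
        cols: list[ColumnInfo] = []
        for name in variables:
            vs = self.schema[name]
            if vs.value_type == "categorical":
                cols.extend(ColumnInfo(name, "onehot", level=lv) for lv in vs.levels)
            elif vs.value_type == "binary":
                cols.append(ColumnInfo(name, "raw"))
            else:
                m, s = self.stats[name]
                role = "logstd" if (vs.value_type == "continuous" and vs.positive) else "std"
                cols.append(ColumnInfo(name, role, shift=m, scale=s))
        return cols

    # -- transforms ---------------------------------------------------------
    def encode_slab(self, wide: pd.DataFrame, variables: list[str]) -> EncodedMatrix:
        """Encode a patients x variables frame (NaN/None = missing)."""
        self._require_fitted()
        cols = self.columns_for(variables)
        n = len(wide)
        X = np.zeros((n, len(cols)))
        M = np.zeros((n, len(cols)), dtype=bool)
        j = 0
        for name in variables:
            vs = self.schema[name]
            col = wide[name] if name in wide.columns else pd.Series([None] * n, index=wide.index)
            if vs.value_type == "categorical":
                K = len(vs.levels)
                obs = col.notna().to_numpy()
                for k, lv in enumerate(vs.levels):
                    X[:, j + k] = (col == lv).to_numpy(dtype=float)
                M[:, j:j + K] = obs[:, None]
                j += K
                continue
            vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            obs = np.isfinite(vals)
            info = cols[j]
            enc = np.zeros(n)
            if info.role == "logstd":
                with np.errstate(invalid="ignore", divide="ignore"):
                    enc[obs] = (np.log(vals[obs]) - info.shift) / info.scale
            elif info.role == "std":
                enc[obs] = (vals[obs] - info.shift) / info.scale
            else:  # raw binary
                enc[obs] = vals[obs]
            X[:, j], M[:, j] = enc, obs
            j += 1
        return EncodedMatrix(X, M, cols, index=list(wide.index.astype(str)))

    def decode_slab(self, X: np.ndarray, variables: list[str]) -> pd.DataFrame:
        """Inverse of :meth:`encode_slab` on fully numeric input."""
        self._require_fitted()
        X = np.atleast_2d(X)
        out: dict[str, object] = {}
        j = 0
        for name in variables:
            vs = self.schema[name]
            if vs.value_type == "categorical":
                K = len(vs.levels)
                idx = np.argmax(X[:, j:j + K], axis=1)
                out[name] = [vs.levels[i] for i in idx]
                j += K
                continue
            m, s = self.stats.get(name, (0.0, 1.0))
            col = X[:, j]
            if vs.value_type == "continuous" and vs.positive:
                vals = np.exp(col * s + m)
            elif vs.value_type == "continuous":
                vals = col * s + m
            elif vs.value_type == "ordinal":
                lo, hi = vs.bounds
                vals = np.clip(np.rint(col * s + m), lo, hi)
            else:  # binary
                vals = np.clip(np.rint(col), 0, 1)
            if vs.value_type == "continuous" and vs.bounds is not None:
                vals = np.clip(vals, *vs.bounds)
            out[name] = vals
            j += 1
        return pd.DataFrame(out)

    def encode_panel(self, cohort: CohortTable) -> EncodedPanel:
        """Encode a cohort into per-visit dynamic arrays plus a static slab."""
        self._require_fitted()
        dyn_vars, static_vars = self.schema.dynamic, self.schema.static
        patients = cohort.patients
        slabs, masks = [], []
        for month in VISIT_MONTHS:
            wide = cohort.wide(month, dyn_vars)
            em = self.encode_slab(wide, dyn_vars)
            slabs.append(em.X)
            masks.append(em.mask)
        st = self.encode_slab(cohort.wide(0, static_vars), static_vars)
        return EncodedPanel(
            dynamic=np.stack(slabs, axis=1), dynamic_mask=np.stack(masks, axis=1),
            static=st.X, static_mask=st.mask, patients=patients,
            dynamic_columns=self.columns_for(dyn_vars),
            static_columns=self.columns_for(static_vars))

    def _require_fitted(self) -> None:
        if not self.fitted:
            raise RuntimeError("Encoder.fit must be called first")


def make_time_pairs(panel: EncodedPanel, keep: str = "any") -> TimePairs:
    """Stack v = [dynamic(t), dynamic(t-1), static] over all visit pairs.

    ``keep`` controls retention of pairs with missing dynamic slabs:
    ``"any"`` (default) keeps pairs with at least one observed dynamic cell,
    ``"all"`` keeps every pair, ``"full"`` keeps only fully observed pairs.
    """
    if keep not in ("any", "all", "full"):
        raise ValueError(f"unknown keep mode {keep!r}")
    P, T, Dd = panel.dynamic.shape
    Xs, Ms, pids, tids = [], [], [], []
    for t in range(1, T):
        X = np.concatenate([panel.dynamic[:, t, :], panel.dynamic[:, t - 1, :],
                            panel.static], axis=1)
        M = np.concatenate([panel.dynamic_mask[:, t, :], panel.dynamic_mask[:, t - 1, :],
                            panel.static_mask], axis=1)
        dyn_obs = M[:, :2 * Dd]
        if keep == "any":
            sel = dyn_obs.any(axis=1)
        elif keep == "full":
            sel = M.all(axis=1)
        else:
            sel = np.ones(P, dtype=bool)
        Xs.append(X[sel])
        Ms.append(M[sel])
        pids.append(np.nonzero(sel)[0])
        tids.append(np.full(sel.sum(), t))
    return TimePairs(X=np.concatenate(Xs), mask=np.concatenate(Ms),
                     patient_idx=np.concatenate(pids), t_idx=np.concatenate(tids),
                     patients=panel.patients)
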