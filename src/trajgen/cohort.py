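"""Long-format cohort tables and the raw-visit preprocessing pipeline.

A cohort is stored long: one row per observed (patient, visit, variable)
cell. Missing observations are simply absent rows, so the missingness mask
is implicit in the table. Raw visit records indexed by study day are mapped
onto the canonical 7-visit grid by 90-day windows centered on each visit.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .schema import ADASCOG11_COMPONENTS, DAYS_PER_MONTH, VISIT_MONTHS, SchemaSet

#: Half-width of the visit assignment window, in days.
WINDOW_HALF_WIDTH_DAYS = 45.0


class CohortValidationError(ValueError):
    pass


class CohortTable:
    """Validated long-format cohort.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``patient_id`` (str), ``visit_month`` (int), ``variable``
        (str), ``value`` (float, or level label for categoricals).
    schema : SchemaSet
        Schema the table conforms to.
    """

    def __init__(self, df: pd.DataFrame, schema: SchemaSet, validate: bool = True):
        required = ["patient_id", "visit_month", "variable", "value"]
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise CohortValidationError(f"missing columns: {missing_cols}")
        df = df[required].copy()
        df["patient_id"] = df["patient_id"].astype(str)
        df["visit_month"] = df["visit_month"].astype(int)
        df["variable"] = df["variable"].astype(str)
        if validate:
            self._validate(df, schema)
        df = df.sort_values(["patient_id", "visit_month", "variable"],
                            kind="stable").reset_index(drop=True)
        self.df = df
        self.schema = schema

    @staticmethod
    def _validate(df: pd.DataFrame, schema: SchemaSet) -> None:
        bad_months = set(df["visit_month"]) - set(VISIT_MONTHS)
        if bad_months:
            raise CohortValidationError(f"non-canonical visit months: {sorted(bad_months)}")
        unknown = set(df["variable"]) - set(schema.names)
        if unknown:
            raise CohortValidationError(f"unknown variables: {sorted(unknown)}")
        dup = df.duplicated(["patient_id", "visit_month", "variable"])
        if dup.any():
            row = df[dup].iloc[0]
            raise CohortValidationError(
                f"duplicate cell ({row.patient_id}, {row.visit_month}, {row.variable})")
        static_off_baseline = df[(df["visit_month"] != 0)
                                 & df["variable"].isin(schema.static)]
        if len(static_off_baseline):
            row = static_off_baseline.iloc[0]
            raise CohortValidationError(
                f"static variable {row.variable} observed at month {row.visit_month}")
        checked = []
        for _, row in df.iterrows():
            try:
                checked.append(schema[row["variable"]].check_value(row["value"]))
            except ValueError as exc:
                raise CohortValidationError(str(exc)) from exc
        df["value"] = checked

    # -- basic queries ------------------------------------------------------
    @property
    def patients(self) -> list[str]:
        return sorted(self.df["patient_id"].unique())

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, patient_ids) -> "CohortTable":
        keep = self.df["patient_id"].isin(set(map(str, patient_ids)))
        return CohortTable(self.df[keep], self.schema, validate=False)

    def wide(self, visit_month: int | None = None,
             variables: list[str] | None = None) -> pd.DataFrame:
        """Patients x variables pivot; NaN (or None) marks missing cells."""
        df = self.df
        if visit_month is not None:
            df = df[df["visit_month"] == visit_month]
        if variables is not None:
            df = df[df["variable"].isin(variables)]
        out = df.pivot(index="patient_id", columns="variable", values="value")
        if variables is not None:
            out = out.reindex(columns=variables)
        return out.reindex(self.patients)

    def equals(self, other: "CohortTable") -> bool:
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        if a.shape != b.shape or not (a[["patient_id", "visit_month", "variable"]]
                                      .equals(b[["patient_id", "visit_month", "variable"]])):
            return False
        va, vb = a["value"].to_numpy(), b["value"].to_numpy()
        for x, y in zip(va, vb):
            if isinstance(x, str) or isinstance(y, str):
                if x != y:
                    return False
            elif not np.isclose(float(x), float(y), rtol=0, atol=1e-12):
                return False
        return True


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_cohort(path: str, schema: SchemaSet) -> CohortTable:
    """Read a long-format cohort CSV (empty value cells are missing)."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise CohortValidationError(f"malformed cohort file {path}: {exc}") from exc
    for col in ("patient_id", "visit_month", "variable", "value"):
        if col not in df.columns:
            raise CohortValidationError(f"{path}: missing column {col!r}")
    df = df[df["value"].str.strip() != ""]
    try:
        df["visit_month"] = df["visit_month"].astype(int)
    except ValueError as exc:
        bad = df[~df["visit_month"].str.fullmatch(r"-?\d+")]
        line = bad.index[0] + 2 if len(bad) else "?"
        raise CohortValidationError(f"{path}: malformed visit_month near line {line}") from exc
    return CohortTable(df, schema)


def write_cohort(cohort: CohortTable, path: str) -> None:
    """Write the standard cohort CSV (inverse of :func:`read_cohort`)."""
    df = cohort.df.copy()
    df["value"] = [v if isinstance(v, str) else format(float(v), ".10g")
                   for v in df["value"]]
    df.to_csv(path, index=False)


def read_raw_visits(path: str) -> pd.DataFrame:
    """Read raw day-indexed visit records (patient_id, day, variable, value)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("patient_id", "day", "variable", "value"):
        if col not in df.columns:
            raise CohortValidationError(f"{path}: missing column {col!r}")
    df = df[df["value"].str.strip() != ""].copy()
    df["day"] = df["day"].astype(float)
    return df


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def visit_window_centers() -> np.ndarray:
    """Day-axis centers of the canonical visits."""
    return np.asarray(VISIT_MONTHS, dtype=float) * DAYS_PER_MONTH


def assign_visit(day: float) -> int | None:
    """Canonical visit month whose 90-day window contains ``day``, else None.

    Windows are half-open on the left, ``(center - 45, center + 45]``, so a
    record exactly 45 days past a center still belongs to that center.
    """
    centers = visit_window_centers()
    inside = (day > centers - WINDOW_HALF_WIDTH_DAYS) & (day <= centers + WINDOW_HALF_WIDTH_DAYS)
    hits = np.nonzero(inside)[0]
    if len(hits) == 0:
        # day 0 boundary: the month-0 window starts at day -45, closed there
        if abs(day - centers[0]) <= WINDOW_HALF_WIDTH_DAYS:
            return VISIT_MONTHS[0]
        return None
    if len(hits) > 1:  # impossible with 45-day half-width and 91-day spacing
        raise RuntimeError(f"day {day} falls in two visit windows")
    return VISIT_MONTHS[hits[0]]


_AGGREGATORS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": np.mean, "min": np.min, "max": np.max,
    "first": lambda a: a[0], "last": lambda a: a[-1],
}


def bucket_visits(raw: pd.DataFrame, schema: SchemaSet,
                  aggregation: Mapping[str, str] | None = None) -> CohortTable:
    """Map day-indexed raw records onto the canonical visit grid.

    Dynamic records are assigned to the visit whose 90-day window contains
    their day (records outside all windows are dropped); multiple records in
    one window are combined by the per-variable aggregation rule (default
    ``mean``; ``min``/``max`` for variables where an extremal value is the
    convention). Static variables are averaged across all their records
    (mode for categoricals) into a single baseline value.
    """
    aggregation = dict(aggregation or {})
    rows = []
    for (pid, var), grp in raw.groupby(["patient_id", "variable"], sort=True):
        if var not in schema:
            raise CohortValidationError(f"unknown variable {var!r}")
        vs = schema[var]
        if vs.temporal == "static":
            if vs.value_type == "categorical":
                counts = grp["value"].value_counts()
                value = counts.index[0]
            else:
                value = float(np.mean([float(x) for x in grp["value"]]))
            rows.append((pid, 0, var, value))
            continue
        agg = _AGGREGATORS[aggregation.get(var, "mean")]
        grp = grp.sort_values("day", kind="stable")
        months = [assign_visit(d) for d in grp["day"]]
        for month in sorted({m for m in months if m is not None}):
            vals = np.asarray([float(v) for v, m in zip(grp["value"], months)
                               if m == month])
            value = float(agg(vals))
            if vs.value_type == "ordinal":
                lo, hi = vs.bounds
                value = float(np.clip(np.rint(value), lo, hi))
            elif vs.value_type == "binary":
                value = float(np.rint(value))
            rows.append((pid, month, var, value))
    df = pd.DataFrame(rows, columns=["patient_id", "visit_month", "variable", "value"])
    return CohortTable(df, schema)


def filter_patients(cohort: CohortTable,
                    months: tuple[int, ...] = (15, 18)) -> CohortTable:
    """Keep patients with a valid ADAS-Cog11 score late in the study.

    A patient is kept when all 11 ADAS-Cog components are observed at any
    single one of the given visit months (default: month 15 or month 18).
    """
    df = cohort.df
    comp = df[df["variable"].isin(ADASCOG11_COMPONENTS)]
    keep: set[str] = set()
    for month in months:
        at_m = comp[comp["visit_month"] == month]
        counts = at_m.groupby("patient_id")["variable"].nunique()
        keep |= set(counts[counts == len(ADASCOG11_COMPONENTS)].index)
    return cohort.subset(sorted(keep))
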