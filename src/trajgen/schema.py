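"""Variable schemas for longitudinal clinical cohorts.

A :class:`VariableSchema` declares everything the rest of the package needs
to know about one clinical variable: its category (cognitive exam component,
laboratory test, clinical measurement, or background covariate), its value
type (binary / ordinal / categorical / continuous), whether it is static or
changes over visits, its bounds or levels, and baseline summary statistics
used as defaults by the synthetic cohort generator.

The packaged default schema describes a 44-variable Alzheimer's/MCI cohort
observed at seven visits (months 0, 3, ..., 18): the 12 ADAS components, 5
MMSE components, 14 laboratory tests, 5 clinical variables (including a
study-dropout indicator), and 8 background covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Iterator, Mapping

import yaml

#: Canonical visit grid in months.
VISIT_MONTHS: tuple[int, ...] = (0, 3, 6, 9, 12, 15, 18)

#: Days per month used to place the canonical visits on a day axis.
DAYS_PER_MONTH: float = 365.25 / 12.0

CATEGORIES = ("ADAS", "MMSE", "laboratory", "clinical", "background")
VALUE_TYPES = ("binary", "ordinal", "categorical", "continuous")
TEMPORAL = ("static", "dynamic")


@dataclass(frozen=True)
class VariableSchema:
    """Declarative description of a single clinical variable.

    Parameters
    ----------
    name : str
        Identifier used in cohort tables.
    category : str
        One of ``ADAS``, ``MMSE``, ``laboratory``, ``clinical``,
        ``background``.
    value_type : str
        One of ``binary``, ``ordinal``, ``categorical``, ``continuous``.
    temporal : str
        ``dynamic`` variables appear at all seven visits, ``static`` ones
        only at baseline.
    levels : tuple of str, optional
        Ordered labels (categorical only).
    bounds : (float, float), optional
        Inclusive value range (ordinal/continuous).
    units : str
        Free-text unit annotation.
    baseline_mean, baseline_sd : float, optional
        Baseline summary statistics; for binary variables ``baseline_mean``
        is the frequency of 1. Used as generator defaults.
    missing_rate : float
        Baseline fraction of missing observations in [0, 1].
    positive : bool
        Continuous variables marked positive are log-transformed before
        standardization when encoded.
    level_probs : tuple of float, optional
        Generator default level frequencies (categorical only).
    """

    name: str
    category: str
    value_type: str
    temporal: str
    levels: tuple[str, ...] | None = None
    bounds: tuple[float, float] | None = None
    units: str = ""
    baseline_mean: float | None = None
    baseline_sd: float | None = None
    missing_rate: float = 0.0
    positive: bool = False
    level_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.name}")
        if self.value_type not in VALUE_TYPES:
            raise ValueError(f"unknown value type {self.value_type!r} for {self.name}")
        if self.temporal not in TEMPORAL:
            raise ValueError(f"unknown temporal role {self.temporal!r} for {self.name}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate out of [0,1] for {self.name}")
        if self.value_type == "categorical":
            if self.levels is None or len(self.levels) < 2:
                raise ValueError(f"categorical variable {self.name} needs >= 2 levels")
            if self.level_probs is not None and len(self.level_probs) != len(self.levels):
                raise ValueError(f"level_probs length mismatch for {self.name}")
        if self.value_type == "ordinal":
            if self.bounds is None:
                raise ValueError(f"ordinal variable {self.name} needs bounds")
            lo, hi = self.bounds
            if not (float(lo).is_integer() and float(hi).is_integer() and lo < hi):
                raise ValueError(f"ordinal bounds must be integers with min < max: {self.name}")
        if self.value_type == "continuous" and self.bounds is not None:
            lo, hi = self.bounds
            if not lo < hi:
                raise ValueError(f"invalid bounds for {self.name}")

    # -- value validation ---------------------------------------------------
    def check_value(self, value: object) -> object:
        """Validate a single observed value, returning its canonical form.

        Numeric values are returned as floats, categorical values as their
        level label. Raises :class:`ValueError` for out-of-schema values.
        """
        if self.value_type == "categorical":
            sval = str(value)
            if sval not in self.levels:  # type: ignore[operator]
                raise ValueError(f"{self.name}: {value!r} is not one of {self.levels}")
            return sval
        fval = float(value)  # may raise ValueError for malformed text
        if self.value_type == "binary":
            if fval not in (0.0, 1.0):
                raise ValueError(f"{self.name}: binary value must be 0 or 1, got {value!r}")
            return fval
        if self.bounds is not None:
            lo, hi = self.bounds
            if not lo <= fval <= hi:
                raise ValueError(f"{self.name}: value {fval} outside bounds [{lo}, {hi}]")
        return fval


class SchemaSet(Mapping[str, VariableSchema]):
    """Ordered collection of :class:`VariableSchema` objects."""

    def __init__(self, variables: Iterable[VariableSchema]):
        self._vars: dict[str, VariableSchema] = {}
        for v in variables:
            if v.name in self._vars:
                raise ValueError(f"duplicate variable {v.name}")
            self._vars[v.name] = v

    def __getitem__(self, name: str) -> VariableSchema:
        return self._vars[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._vars)

    def __len__(self) -> int:
        return len(self._vars)

    @property
    def names(self) -> list[str]:
        return list(self._vars)

    @property
    def dynamic(self) -> list[str]:
        return [n for n, v in self._vars.items() if v.temporal == "dynamic"]

    @property
    def static(self) -> list[str]:
        return [n for n, v in self._vars.items() if v.temporal == "static"]

    def by_category(self, category: str) -> list[str]:
        return [n for n, v in self._vars.items() if v.category == category]

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path: str) -> None:
        entries = []
        for v in self._vars.values():
            d = asdict(v)
            d = {k: (list(x) if isinstance(x, tuple) else x) for k, x in d.items()
                 if x is not None}
            entries.append(d)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"variables": entries}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SchemaSet":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        variables = []
        for entry in doc["variables"]:
            for key in ("levels", "bounds", "level_probs"):
                if entry.get(key) is not None:
                    entry[key] = tuple(entry[key])
            variables.append(VariableSchema(**entry))
        return cls(variables)


# ---------------------------------------------------------------------------
# Default 44-variable AD/MCI schema.
# Baseline means/SDs, level frequencies and missingness rates summarize a
# pooled MCI/AD clinical-trial population at study entry.
# ---------------------------------------------------------------------------

def _adas(name: str, mean: float, sd: float, hi: int, miss: float) -> VariableSchema:
    return VariableSchema(name, "ADAS", "ordinal", "dynamic", bounds=(0, hi),
                          baseline_mean=mean, baseline_sd=sd, missing_rate=miss / 100.0)


def _mmse(name: str, mean: float, sd: float, hi: int) -> VariableSchema:
    return VariableSchema(name, "MMSE", "ordinal", "dynamic", bounds=(0, hi),
                          baseline_mean=mean, baseline_sd=sd, missing_rate=0.168)


def _lab(name: str, mean: float, sd: float, units: str, miss: float) -> VariableSchema:
    return VariableSchema(name, "laboratory", "continuous", "dynamic", units=units,
                          baseline_mean=mean, baseline_sd=sd, missing_rate=miss / 100.0,
                          positive=True)


_DEFAULT_VARIABLES: tuple[VariableSchema, ...] = (
    # ADAS components (ordinal, dynamic)
    _adas("adas_commands", 0.58, 0.84, 5, 0.1),
    _adas("adas_comprehension", 0.40, 0.72, 5, 0.1),
    _adas("adas_construction", 0.94, 0.90, 5, 0.1),
    _adas("adas_delayed_word_recall", 7.94, 2.51, 10, 0.4),
    _adas("adas_ideational", 0.54, 0.88, 5, 0.1),
    _adas("adas_instructions", 0.78, 1.18, 5, 0.1),
    _adas("adas_naming", 0.67, 0.88, 5, 0.1),
    _adas("adas_orientation", 2.48, 2.02, 8, 0.1),
    _adas("adas_spoken_language", 0.30, 0.69, 5, 0.1),
    _adas("adas_word_finding", 0.66, 0.90, 5, 0.1),
    _adas("adas_word_recall", 6.04, 1.78, 10, 0.1),
    _adas("adas_word_recognition", 6.35, 3.30, 12, 0.1),
    # MMSE components (ordinal, dynamic)
    _mmse("mmse_attention_calculation", 2.88, 1.69, 5),
    _mmse("mmse_language", 7.90, 0.92, 9),
    _mmse("mmse_orientation", 6.56, 1.92, 10),
    _mmse("mmse_recall", 0.82, 0.88, 3),
    _mmse("mmse_registration", 2.90, 0.34, 3),
    # Laboratory tests (continuous positive, dynamic)
    _lab("alanine_aminotransferase", 0.32, 0.14, "ukat/l", 18.2),
    _lab("alkaline_phosphatase", 1.29, 0.46, "ukat/l", 18.2),
    _lab("aspartate_aminotransferase", 0.37, 0.10, "ukat/l", 18.2),
    _lab("cholesterol", 5.5, 1.0, "mmol/l", 17.9),
    _lab("creatine_kinase", 0.99, 0.62, "mg/dl", 0.7),
    _lab("creatinine", 0.95, 0.22, "mg/dl", 17.9),
    _lab("gamma_glutamyl_transferase", 2.3, 1.8, "iu/dl", 32.0),
    _lab("hematocrit", 0.42, 0.04, "fraction", 14.7),
    _lab("hemoglobin", 14.0, 1.2, "g/dl", 0.8),
    _lab("hemoglobin_a1c", 5.81, 0.73, "%", 48.4),
    _lab("indirect_bilirubin", 0.51, 0.24, "mg/dl", 48.4),
    _lab("potassium", 4.34, 0.35, "mmol/l", 18.0),
    _lab("sodium", 1.41, 0.02, "mmol/cl", 31.8),
    _lab("triglycerides", 1.53, 0.83, "g/l", 18.1),
    # Clinical variables (dynamic)
    VariableSchema("bp_diastolic", "clinical", "continuous", "dynamic", units="mmHg",
                   baseline_mean=75.9, baseline_sd=8.3, missing_rate=0.018, positive=True),
    VariableSchema("bp_systolic", "clinical", "continuous", "dynamic", units="mmHg",
                   baseline_mean=135.0, baseline_sd=15.0, missing_rate=0.018, positive=True),
    VariableSchema("heart_rate", "clinical", "continuous", "dynamic", units="bpm",
                   baseline_mean=67.3, baseline_sd=8.2, missing_rate=0.018, positive=True),
    VariableSchema("weight", "clinical", "continuous", "dynamic", units="kg",
                   baseline_mean=71.0, baseline_sd=15.0, missing_rate=0.030, positive=True),
    VariableSchema("dropout", "clinical", "binary", "dynamic",
                   baseline_mean=0.0, missing_rate=0.001),
    # Background covariates (static)
    VariableSchema("age", "background", "continuous", "static", units="years",
                   baseline_mean=73.4, baseline_sd=8.4, missing_rate=0.009, positive=True),
    VariableSchema("geographic_region", "background", "categorical", "static",
                   levels=("north_america", "europe", "other"),
                   level_probs=(0.67, 0.22, 0.11)),
    VariableSchema("initial_diagnosis", "background", "binary", "static",
                   baseline_mean=0.69),  # 1 = AD, 0 = MCI
    VariableSchema("cardiovascular_event", "background", "binary", "static",
                   baseline_mean=0.37),
    VariableSchema("apoe4_count", "background", "ordinal", "static", bounds=(0, 2),
                   baseline_mean=0.80, baseline_sd=0.69, missing_rate=0.724),
    VariableSchema("race", "background", "categorical", "static",
                   levels=("white", "black", "asian", "other"),
                   level_probs=(0.93, 0.04, 0.02, 0.01), missing_rate=0.002),
    VariableSchema("sex", "background", "binary", "static",
                   baseline_mean=0.54),  # 1 = F, 0 = M
    VariableSchema("height", "background", "continuous", "static", units="cm",
                   baseline_mean=165.0, baseline_sd=10.0, missing_rate=0.019, positive=True),
)

#: The 11 ADAS components whose sum is the ADAS-Cog11 total. Delayed word
#: recall is tracked in the schema but is not part of the 11-component score.
ADASCOG11_COMPONENTS: tuple[str, ...] = tuple(
    v.name for v in _DEFAULT_VARIABLES
    if v.category == "ADAS" and v.name != "adas_delayed_word_recall"
)


def default_schema() -> SchemaSet:
    """The packaged 44-variable AD/MCI cohort schema."""
    return SchemaSet(_DEFAULT_VARIABLES)
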