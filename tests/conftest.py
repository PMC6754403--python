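"""Shared fixtures: tiny cohorts, enumerable toy models, reference models."""

import numpy as np
import pandas as pd
import pytest

from trajgen import (CohortTable, CRBMParams, Encoder, SchemaSet, VariableSchema,
                     VisibleLayout, simple_layout, synthetic)


@pytest.fixture(scope="session")
def small_schema() -> SchemaSet:
    """Mixed-type mini schema: 2 dynamic + 2 static variables."""
    return SchemaSet([
        VariableSchema("score", "ADAS", "ordinal", "dynamic", bounds=(0, 10),
                       baseline_mean=4.0, baseline_sd=2.0),
        VariableSchema("marker", "laboratory", "continuous", "dynamic",
                       baseline_mean=2.0, baseline_sd=0.5, positive=True),
        VariableSchema("sex", "background", "binary", "static", baseline_mean=0.5),
        VariableSchema("site", "background", "categorical", "static",
                       levels=("a", "b", "c"), level_probs=(0.5, 0.3, 0.2)),
    ])


@pytest.fixture
def small_cohort(small_schema) -> CohortTable:
    rows = []
    for i, pid in enumerate(["p1", "p2", "p3"]):
        rows.append((pid, 0, "sex", float(i % 2)))
        rows.append((pid, 0, "site", ["a", "b", "c"][i]))
        for t in (0, 3, 6):
            rows.append((pid, t, "score", float(2 + i + t // 3)))
            if not (pid == "p2" and t == 3):  # one missing marker cell
                rows.append((pid, t, "marker", 1.5 + 0.1 * i + 0.05 * t))
    df = pd.DataFrame(rows, columns=["patient_id", "visit_month", "variable", "value"])
    return CohortTable(df, small_schema)


@pytest.fixture(scope="session")
def toy_binary_params() -> CRBMParams:
    """Enumerable 3-binary-visible / 2-hidden model with moderate couplings."""
    rng = np.random.default_rng(42)
    lay = simple_layout([("binary", 1)] * 3)
    return CRBMParams(lay, rng.normal(0, 0.8, (3, 2)), rng.normal(0, 0.5, 3),
                      np.array([0.3, -0.2]), np.ones(3), np.array([1.0, 0.7]))


@pytest.fixture(scope="session")
def tiny_slab_model():
    """Enumerable all-binary model with the [t, t-1, static] slab layout."""
    schema = SchemaSet([
        VariableSchema("d0", "clinical", "binary", "dynamic"),
        VariableSchema("d1", "clinical", "binary", "dynamic"),
        VariableSchema("s0", "background", "binary", "static"),
    ])
    encoder = Encoder(schema).set_identity_stats()
    layout = VisibleLayout.from_columns(
        encoder.columns_for(schema.dynamic), encoder.columns_for(schema.static),
        {v: schema[v].value_type for v in schema.names})
    rng = np.random.default_rng(5)
    params = CRBMParams(layout, rng.normal(0, 0.7, (5, 2)), rng.normal(0, 0.4, 5),
                        np.array([0.1, -0.3]), np.ones(5), np.ones(2))
    return params, encoder


@pytest.fixture(scope="session")
def reference_model():
    """Continuous-variable reference model used as simulation ground truth."""
    return synthetic.reference_crbm(seed=3)
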