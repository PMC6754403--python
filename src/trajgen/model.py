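"""Model/Results facade tying preprocessing, fitting, and simulation together.

Usage follows the fit-and-results convention of statistical modelling
packages::

    cohort = read_cohort("cohort.csv", default_schema())
    model = CRBM(cohort, n_hidden=50)
    res = model.fit(TrainConfig(n_epochs=200, seed=1))
    print(res.summary())
    trajs = res.simulate(baselines=test_cohort, n_replicates=100, seed=2)
    moments = res.conditional_moments(test_cohort, seed=3)

The model object owns the frozen encoder (standardization statistics from
the training patients), the visible layout, and the stacked training
vectors; the results object owns the fitted parameters, training history,
and every simulation/evaluation entry point. ``save``/``load`` round-trip
the fitted model through a structured JSON artifact.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import simulation, training
from .cohort import CohortTable
from .crbm import CRBMParams, VisibleLayout
from .encoding import Encoder, make_time_pairs
from .schema import SchemaSet, VariableSchema
from .training import TrainConfig


class CRBM:
    """Conditional restricted Boltzmann machine over a longitudinal cohort.

    Parameters
    ----------
    cohort : CohortTable
        Training data (already preprocessed onto the canonical visit grid).
    train_patients : list of str, optional
        Restrict encoder statistics and training vectors to these patients
        (e.g. the training split of a CV fold). Defaults to all patients.
    n_hidden : int
        Number of rectified latent units.
    keep : str
        Retention rule for visit pairs with missing dynamic slabs
        (see ``encoding.make_time_pairs``).
    """

    def __init__(self, cohort: CohortTable, train_patients: list[str] | None = None,
                 n_hidden: int = 50, keep: str = "any"):
        self.cohort = cohort
        self.schema = cohort.schema
        self.n_hidden = n_hidden
        train = cohort if train_patients is None else cohort.subset(train_patients)
        self.encoder = Encoder(self.schema).fit(train)
        panel = self.encoder.encode_panel(train)
        self.pairs = make_time_pairs(panel, keep=keep)
        self.layout = VisibleLayout.from_columns(
            panel.dynamic_columns, panel.static_columns,
            {v: self.schema[v].value_type for v in self.schema.names})

    @property
    def exog_names(self) -> list[str]:
        return [g.name for g in self.layout.groups]

    def fit(self, config: TrainConfig | None = None, **overrides) -> "CRBMResults":
        """Fit by stochastic maximum likelihood (+ optional adversarial term)."""
        if config is None:
            config = TrainConfig(n_hidden=self.n_hidden, **overrides)
        elif overrides:
            config = TrainConfig(**{**asdict(config), **overrides})
        if config.n_hidden != self.n_hidden:
            config = TrainConfig(**{**asdict(config), "n_hidden": self.n_hidden})
        params, history = training.fit(self.pairs.X, self.pairs.mask,
                                       self.layout, config)
        return CRBMResults(self, params, history, config)


class CRBMResults:
    """Fitted model: parameters, history, simulation and scoring."""

    def __init__(self, model: CRBM | None, params: CRBMParams,
                 history: pd.DataFrame | None = None,
                 config: TrainConfig | None = None,
                 encoder: Encoder | None = None):
        self.model = model
        self.params = params
        self.history = history
        self.config = config
        self.encoder = encoder if encoder is not None else model.encoder

    @property
    def schema(self) -> SchemaSet:
        return self.encoder.schema

    # -- scoring ------------------------------------------------------------
    def validate(self, cohort: CohortTable,
                 patients: list[str] | None = None) -> float:
        """Mean predictive log-likelihood of observed cells (higher better)."""
        sub = cohort if patients is None else cohort.subset(patients)
        panel = self.encoder.encode_panel(sub)
        pairs = make_time_pairs(panel, keep="any")
        return training.validate(self.params, pairs.X, pairs.mask)

    # -- simulation ---------------------------------------------------------
    def simulate(self, baselines: CohortTable | None = None, n_patients: int = 0,
                 n_replicates: int = 1, horizon_visits: int = 6, seed: int = 0,
                 gibbs_steps: int = simulation.DEFAULT_GIBBS_STEPS
                 ) -> simulation.TrajectorySet:
        """Type-i trajectories when ``baselines`` is given, else type-ii."""
        if baselines is not None:
            return simulation.simulate_from_baseline(
                self.params, self.encoder, baselines, horizon_visits=horizon_visits,
                n_replicates=n_replicates, seed=seed, gibbs_steps=gibbs_steps)
        return simulation.simulate_de_novo(self.params, self.encoder, n_patients,
                                           seed=seed, gibbs_steps=gibbs_steps)

    def conditional_moments(self, baselines: CohortTable,
                            visits: list[int] | None = None,
                            n_replicates: int = 100, seed: int = 0) -> pd.DataFrame:
        return simulation.conditional_moments(self.params, self.encoder, baselines,
                                              visits=visits,
                                              n_replicates=n_replicates, seed=seed)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        lines = ["Conditional RBM results", "=" * 46]
        lines.append(f"visible units:        {self.params.n_visible}")
        lines.append(f"hidden units:         {self.params.n_hidden}")
        lines.append(f"dynamic variables:    {len(self.schema.dynamic)}")
        lines.append(f"static variables:     {len(self.schema.static)}")
        if self.model is not None:
            lines.append(f"training vectors:     {self.model.pairs.X.shape[0]}")
            obs = self.model.pairs.mask.mean()
            lines.append(f"observed cell frac:   {obs:.3f}")
        if self.config is not None:
            lines.append(f"epochs:               {self.config.n_epochs}")
            lines.append(f"adversarial weight:   {self.config.adversarial_weight}")
            lines.append(f"seed:                 {self.config.seed}")
        if self.history is not None and len(self.history):
            last = self.history.iloc[-1]
            lines.append(f"final free energy (data):  {last.free_energy_data:.4f}")
            lines.append(f"final free energy (model): {last.free_energy_model:.4f}")
            lines.append(f"final critic gap:          {last.critic_gap:.4f}")
        w = self.params.W
        lines.append(f"|W| mean / max:       {np.abs(w).mean():.4f} / {np.abs(w).max():.4f}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------
    def save(self, path: str) -> None:
        """Serialize parameters, encoder transforms, and schema to JSON."""
        doc = {
            "params": self.params.to_dict(),
            "encoder_stats": self.encoder.stats,
            "schema": [
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(self.schema[name]).items() if v is not None}
                for name in self.schema.names],
            "config": None if self.config is None else asdict(self.config),
            "history": None if self.history is None
            else self.history.to_dict(orient="list"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, default=float)

    @classmethod
    def load(cls, path: str) -> "CRBMResults":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        variables = []
        for entry in doc["schema"]:
            for key in ("levels", "bounds", "level_probs"):
                if entry.get(key) is not None:
                    entry[key] = tuple(entry[key])
            variables.append(VariableSchema(**entry))
        schema = SchemaSet(variables)
        encoder = Encoder(schema)
        encoder.stats = {k: tuple(v) for k, v in doc["encoder_stats"].items()}
        encoder.fitted = True
        params = CRBMParams.from_dict(doc["params"])
        config = None if doc["config"] is None else TrainConfig(**doc["config"])
        history = None if doc["history"] is None else pd.DataFrame(doc["history"])
        return cls(None, params, history, config, encoder=encoder)
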