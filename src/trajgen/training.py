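"""Model fitting: stochastic maximum likelihood with persistent chains,
automated imputation of missing training coordinates, an optional
adversarial penalty, and the patient-level cross-validation plan.

The likelihood gradient of the energy model is the difference between
data-phase and model-phase expectations of the sufficient statistics; the
model phase is estimated from persistent Gibbs chains retained across
minibatches. Hidden activations are Rao-Blackwellized (the conditional mean
of the truncated normal is used instead of a sample) in both phases.

Missing coordinates in a minibatch are imputed before each gradient step by
drawing from p(v_missing | v_observed) under the current parameters, so
observed coordinates are never overwritten.

The adversarial penalty is a deliberately simple variant of
adversarial-distinguishability regularization: a linear critic on hidden
activations is refit periodically to the direction separating data-phase
from model-phase batches, and the squared gap between mean critic scores is
penalized through its model-phase gradient (a covariance between the critic
score and the sufficient statistics over the chains). Setting the weight to
zero recovers pure stochastic maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from . import crbm
from .crbm import CRBMParams, VisibleLayout


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyperparameters for :func:`fit`.

    ``adversarial_weight`` = 0 gives pure stochastic maximum likelihood.
    """
    n_hidden: int = 50
    minibatch: int = 128
    learning_rate: float = 5e-3
    lr_decay: float = 0.98          # geometric decay applied per epoch
    n_epochs: int = 100
    n_chains: int = 100
    mc_steps: int = 1               # Gibbs steps advancing the chains per gradient
    adversarial_weight: float = 0.1
    critic_refit_every: int = 10    # minibatches between critic refits
    impute_steps: int = 5           # Gibbs refresh steps for missing coordinates
    w_init: float = 0.01
    average_from: float | None = None  # tail-average params from this epoch fraction
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hidden", "minibatch", "n_epochs", "n_chains", "mc_steps",
                     "critic_refit_every", "impute_steps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.adversarial_weight < 0:
            raise ValueError("adversarial_weight must be >= 0")


@dataclass
class CVPlan:
    """Patient-level train/validation/test split for each fold."""
    folds: list[dict[str, list[str]]] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_cv_plan(patient_ids: list[str], seed: int, n_folds: int = 5,
                 validation_fraction: float = 0.05) -> CVPlan:
    """Deterministic patient-level k-fold plan (~75/5/20 train/val/test).

    Every patient is in the test set of exactly one fold; within a fold the
    three sets partition the cohort. Splits are by patient, never by visit.
    """
    ids = [str(p) for p in patient_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} patients")
    rng = np.random.default_rng(seed)
    order = list(np.array(sorted(ids))[rng.permutation(len(ids))])
    test_folds = [list(chunk) for chunk in np.array_split(order, n_folds)]
    n_val = max(1, int(round(validation_fraction * len(ids))))
    folds = []
    for k in range(n_folds):
        test = test_folds[k]
        rest = [p for p in order if p not in set(test)]
        validation, train = rest[:n_val], rest[n_val:]
        folds.append({"train": train, "validation": validation, "test": test})
    return CVPlan(folds)


# ---------------------------------------------------------------------------
# Sufficient statistics
# ---------------------------------------------------------------------------

def _linear_cols(layout: VisibleLayout) -> np.ndarray:
    parts = [layout.binary_cols] + list(layout.onehot_groups)
    parts = [p for p in parts if len(p)]
    return np.concatenate(parts) if parts else np.array([], dtype=int)


def _phase_stats(V: np.ndarray, H: np.ndarray, params: CRBMParams,
                 weights: np.ndarray | None = None):
    """Per-parameter expected sufficient statistics of one phase.

    With ``weights`` (zero-mean over the batch) this returns covariances
    between the weight series and the statistics instead of plain means —
    used by the adversarial penalty.
    """
    sig2, eps2 = params.sigma ** 2, params.epsilon ** 2
    n = V.shape[0]
    w = np.full(n, 1.0 / n) if weights is None else weights / n
    Vw = V * w[:, None]
    sW = (Vw / sig2).T @ (H / eps2)
    svb = np.zeros(params.n_visible)
    g = params.layout.gaussian_cols
    if len(g):
        svb[g] = ((Vw[:, g]).sum(axis=0) - w.sum() * params.vis_bias[g]) / sig2[g]
    lin = _linear_cols(params.layout)
    if len(lin):
        svb[lin] = Vw[:, lin].sum(axis=0)
    sth = ((H * w[:, None]).sum(axis=0) - w.sum() * params.hid_loc) / eps2
    return sW, svb, sth


def _init_from_data(X: np.ndarray, mask: np.ndarray, layout: VisibleLayout,
                    n_hidden: int, w_init: float, rng: np.random.Generator) -> CRBMParams:
    n_vis = layout.n_cols
    vis_bias = np.zeros(n_vis)
    with np.errstate(invalid="ignore"):
        col_mean = np.where(mask.sum(axis=0) > 0,
                            (X * mask).sum(axis=0) / np.maximum(mask.sum(axis=0), 1), 0.0)
    g = layout.gaussian_cols
    vis_bias[g] = col_mean[g]
    b = layout.binary_cols
    vis_bias[b] = special.logit(np.clip(col_mean[b], 0.01, 0.99))
    for grp in layout.onehot_groups:
        freq = np.clip(col_mean[grp], 1e-3, None)
        vis_bias[grp] = np.log(freq / freq.sum())
    W = rng.normal(0.0, w_init, size=(n_vis, n_hidden))
    return CRBMParams(layout, W, vis_bias, np.zeros(n_hidden),
                      np.ones(n_vis), np.ones(n_hidden))


def _impute_batch(V: np.ndarray, M: np.ndarray, params: CRBMParams,
                  n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Fill missing coordinates by conditional sampling; observed cells kept."""
    rows = ~M.all(axis=1)
    if not rows.any():
        return V
    V = V.copy()
    sub, msub = V[rows], M[rows]
    init = crbm.sample_bias_only(params, sub.shape[0], rng)
    start = np.where(msub, sub, init)
    V[rows] = crbm.gibbs_sample(start, msub, params, n_steps, rng)
    return V


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit(X: np.ndarray, mask: np.ndarray | None, layout: VisibleLayout,
        config: TrainConfig) -> tuple[CRBMParams, pd.DataFrame]:
    """Fit model parameters on training vectors with a missingness mask.

    Returns the fitted :class:`CRBMParams` and a per-epoch history frame
    (data/model free energy on a fixed probe subsample, critic gap, gradient
    norm). Fully reproducible from ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("empty or malformed training set")
    mask = np.ones(X.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    rng = np.random.default_rng(config.seed)
    params = _init_from_data(X, mask, layout, config.n_hidden, config.w_init, rng)

    chains = crbm.sample_bias_only(params, config.n_chains, rng)
    critic = np.zeros(config.n_hidden)
    critic_gap = 0.0
    n = X.shape[0]
    probe = rng.permutation(n)[:min(n, 512)]
    history = []
    lam = config.adversarial_weight
    batches_seen = 0
    # optional tail averaging over late epochs smooths stochastic-gradient noise
    avg_start = (None if config.average_from is None
                 else int(config.average_from * config.n_epochs))
    avg_acc, avg_count = None, 0

    for epoch in range(config.n_epochs):
        lr = config.learning_rate * config.lr_decay ** epoch
        order = rng.permutation(n)
        grad_norm = 0.0
        for start in range(0, n, config.minibatch):
            idx = order[start:start + config.minibatch]
            V = _impute_batch(X[idx], mask[idx], params, config.impute_steps, rng)
            Hd = crbm.hidden_mean(V, params)
            chains = crbm.gibbs_sample(chains, None, params, config.mc_steps, rng)
            Hm = crbm.hidden_mean(chains, params)

            dW, dvb, dth = _phase_stats(V, Hd, params)
            mW, mvb, mth = _phase_stats(chains, Hm, params)
            gW, gvb, gth = dW - mW, dvb - mvb, dth - mth

            if lam > 0:
                if batches_seen % config.critic_refit_every == 0:
                    direction = Hd.mean(axis=0) - Hm.mean(axis=0)
                    norm = np.linalg.norm(direction)
                    critic = direction / norm if norm > 0 else critic
                s_data = Hd @ critic
                s_model = Hm @ critic
                critic_gap = float(s_data.mean() - s_model.mean())
                centered = s_model - s_model.mean()
                cW, cvb, cth = _phase_stats(chains, Hm, params, weights=centered)
                gW += lam * critic_gap * cW
                gvb += lam * critic_gap * cvb
                gth += lam * critic_gap * cth

            for gr in (gW, gvb, gth):
                if not np.all(np.isfinite(gr)):
                    raise RuntimeError(
                        f"non-finite gradient at epoch {epoch}; reduce the learning rate")
            params.W += lr * gW
            params.vis_bias += lr * gvb
            params.hid_loc += lr * gth
            grad_norm = float(np.sqrt((gW ** 2).sum() + (gvb ** 2).sum()
                                      + (gth ** 2).sum()))
            batches_seen += 1

        fe_data = float(np.mean(-crbm.log_unnormalized_marginal(
            _impute_batch(X[probe], mask[probe], params, config.impute_steps, rng),
            params)))
        fe_model = float(np.mean(-crbm.log_unnormalized_marginal(chains, params)))
        history.append({"epoch": epoch, "free_energy_data": fe_data,
                        "free_energy_model": fe_model, "critic_gap": critic_gap,
                        "grad_norm": grad_norm, "learning_rate": lr})
        if avg_start is not None and epoch >= avg_start:
            if avg_acc is None:
                avg_acc = [params.W.copy(), params.vis_bias.copy(),
                           params.hid_loc.copy()]
            else:
                avg_acc[0] += params.W
                avg_acc[1] += params.vis_bias
                avg_acc[2] += params.hid_loc
            avg_count += 1
    if avg_acc is not None:
        params.W = avg_acc[0] / avg_count
        params.vis_bias = avg_acc[1] / avg_count
        params.hid_loc = avg_acc[2] / avg_count
    return params, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# Validation score
# ---------------------------------------------------------------------------

def validate(params: CRBMParams, X: np.ndarray,
             mask: np.ndarray | None = None) -> float:
    """Mean per-coordinate predictive log-likelihood of observed cells.

    Each observed cell is scored under its single-unit conditional given the
    Rao-Blackwellized hidden activation of the full vector (a standard
    pseudo-likelihood surrogate). Higher is better.
    """
    X = np.asarray(X, dtype=float)
    mask = np.ones(X.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    H = crbm.hidden_mean(np.where(mask, X, 0.0), params)
    spec = crbm.visible_conditional(H, params)
    total, count = 0.0, 0
    g = spec["gaussian_cols"]
    if len(g):
        mg = mask[:, g]
        z = (X[:, g] - spec["gaussian_mean"]) / spec["gaussian_sd"]
        ll = -0.5 * z ** 2 - np.log(spec["gaussian_sd"] * np.sqrt(2 * np.pi))
        total += ll[mg].sum()
        count += int(mg.sum())
    b = spec["binary_cols"]
    if len(b):
        mb = mask[:, b]
        p = np.clip(spec["binary_p"], 1e-12, 1 - 1e-12)
        ll = X[:, b] * np.log(p) + (1 - X[:, b]) * np.log(1 - p)
        total += ll[mb].sum()
        count += int(mb.sum())
    for grp, p in zip(spec["onehot_groups"], spec["onehot_p"]):
        mo = mask[:, grp].all(axis=1)
        if mo.any():
            ll = np.log(np.clip((X[:, grp] * p).sum(axis=1), 1e-12, None))
            total += ll[mo].sum()
            count += int(mo.sum())
    if count == 0:
        raise ValueError("no observed cells to score")
    return total / count
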