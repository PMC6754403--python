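"""Energy-based model core: mixed-type restricted Boltzmann machine with
rectified (zero-truncated normal) hidden units.

The joint density over a visible vector v and hidden vector h >= 0 is

    p(v, h) = Z^{-1} exp( sum_j a_j(v_j) + sum_mu b_mu(h_mu)
                          + sum_{j,mu} W_{j mu} (v_j / sigma_j^2)(h_mu / eps_mu^2) )

with per-unit terms chosen by data type: a_j(v) = c_j v for binary and
one-hot units, a_j(v) = -(v - nu_j)^2 / (2 sigma_j^2) for continuous units,
and b_mu(h) = -(h - theta_mu)^2 / (2 eps_mu^2) on h >= 0 for the hidden
layer. These are the canonical exponential-family forms compatible with the
bilinear interaction; they give closed-form layer conditionals:

* h_mu | v  ~ Normal(theta_mu + sum_j W_{j mu} v_j / sigma_j^2, eps_mu)
  truncated below at zero (conditionally independent across mu);
* continuous v_j | h ~ Normal(nu_j + J_j, sigma_j) with
  J_j = sum_mu W_{j mu} h_mu / eps_mu^2;
* binary v_j | h ~ Bernoulli with log-odds c_j + J_j / sigma_j^2;
* one-hot groups | h ~ categorical via softmax of c_l + J_l / sigma_l^2.

For models whose visible layer is entirely binary/one-hot the hidden layer
can be integrated out in closed form (a Gaussian tail integral per hidden
unit), which yields an exact marginal over the enumerable visible states —
the oracle used to validate the Gibbs sampler and training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.stats import truncnorm

from .encoding import ColumnInfo

_SQRT_2PI = np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VisibleGroup:
    """A visible unit (or one-hot block): name, type, columns, time slab."""
    name: str
    kind: str                   # 'gaussian' | 'binary' | 'onehot'
    cols: tuple[int, ...]
    slab: str = ""              # 't' | 'tm1' | 'static' | ''


class VisibleLayout:
    """Maps encoded columns to typed visible units with time-slab tags."""

    def __init__(self, groups: list[VisibleGroup]):
        cols = [c for g in groups for c in g.cols]
        n = len(cols)
        if sorted(cols) != list(range(n)):
            raise ValueError("layout must cover every column exactly once")
        for g in groups:
            if g.kind not in ("gaussian", "binary", "onehot"):
                raise ValueError(f"unknown unit kind {g.kind!r}")
            if g.kind == "onehot" and len(g.cols) < 2:
                raise ValueError(f"one-hot group {g.name} needs >= 2 levels")
            if g.kind in ("gaussian", "binary") and len(g.cols) != 1:
                raise ValueError(f"{g.kind} unit {g.name} must own exactly one column")
        self.groups = list(groups)
        self.n_cols = n
        self.gaussian_cols = np.array([g.cols[0] for g in groups if g.kind == "gaussian"],
                                      dtype=int)
        self.binary_cols = np.array([g.cols[0] for g in groups if g.kind == "binary"],
                                    dtype=int)
        self.onehot_groups = [np.array(g.cols, dtype=int) for g in groups
                              if g.kind == "onehot"]

    def slab_cols(self, slab: str) -> np.ndarray:
        return np.array([c for g in self.groups if g.slab == slab for c in g.cols],
                        dtype=int)

    @classmethod
    def from_columns(cls, dynamic_cols: list[ColumnInfo],
                     static_cols: list[ColumnInfo],
                     value_types: dict[str, str]) -> "VisibleLayout":
        """Build the [dynamic(t), dynamic(t-1), static] layout from column maps."""
        groups: list[VisibleGroup] = []
        offset = 0
        for slab, cols in (("t", dynamic_cols), ("tm1", dynamic_cols),
                           ("static", static_cols)):
            j = offset
            i = 0
            while i < len(cols):
                info = cols[i]
                if info.role == "onehot":
                    span = [k for k in range(i, len(cols))
                            if cols[k].variable == info.variable]
                    groups.append(VisibleGroup(f"{info.variable}@{slab}", "onehot",
                                               tuple(range(j, j + len(span))), slab))
                    i += len(span)
                    j += len(span)
                    continue
                kind = "binary" if value_types[info.variable] == "binary" else "gaussian"
                groups.append(VisibleGroup(f"{info.variable}@{slab}", kind, (j,), slab))
                i += 1
                j += 1
            offset = j
        return cls(groups)

    def to_dict(self) -> dict:
        return {"groups": [{"name": g.name, "kind": g.kind,
                            "cols": list(g.cols), "slab": g.slab}
                           for g in self.groups]}

    @classmethod
    def from_dict(cls, d: dict) -> "VisibleLayout":
        return cls([VisibleGroup(g["name"], g["kind"], tuple(g["cols"]), g["slab"])
                    for g in d["groups"]])


def simple_layout(kinds: list[tuple[str, int]]) -> VisibleLayout:
    """Layout helper for small untagged models, e.g. [('binary', 1), ...]."""
    groups, j = [], 0
    for i, (kind, width) in enumerate(kinds):
        groups.append(VisibleGroup(f"u{i}", kind, tuple(range(j, j + width))))
        j += width
    return VisibleLayout(groups)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class CRBMParams:
    """All learned quantities of the model.

    ``vis_bias`` holds c_j for binary/one-hot columns and the location nu_j
    for continuous columns; ``hid_loc`` holds theta_mu. ``sigma`` and
    ``epsilon`` are the per-unit scales (strictly positive).
    """
    layout: VisibleLayout
    W: np.ndarray               # (n_vis, n_hid)
    vis_bias: np.ndarray        # (n_vis,)
    hid_loc: np.ndarray         # (n_hid,)
    sigma: np.ndarray           # (n_vis,)
    epsilon: np.ndarray         # (n_hid,)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.vis_bias = np.asarray(self.vis_bias, dtype=float)
        self.hid_loc = np.asarray(self.hid_loc, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        n_vis, n_hid = self.W.shape
        if n_vis != self.layout.n_cols:
            raise ValueError("W rows must match layout columns")
        if self.vis_bias.shape != (n_vis,) or self.sigma.shape != (n_vis,):
            raise ValueError("visible parameter shape mismatch")
        if self.hid_loc.shape != (n_hid,) or self.epsilon.shape != (n_hid,):
            raise ValueError("hidden parameter shape mismatch")
        if np.any(self.sigma <= 0) or np.any(self.epsilon <= 0):
            raise ValueError("scales sigma and epsilon must be strictly positive")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "CRBMParams":
        return CRBMParams(self.layout, self.W.copy(), self.vis_bias.copy(),
                          self.hid_loc.copy(), self.sigma.copy(), self.epsilon.copy())

    def to_dict(self) -> dict:
        return {"layout": self.layout.to_dict(), "W": self.W.tolist(),
                "vis_bias": self.vis_bias.tolist(), "hid_loc": self.hid_loc.tolist(),
                "sigma": self.sigma.tolist(), "epsilon": self.epsilon.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "CRBMParams":
        return cls(VisibleLayout.from_dict(d["layout"]), np.array(d["W"]),
                   np.array(d["vis_bias"]), np.array(d["hid_loc"]),
                   np.array(d["sigma"]), np.array(d["epsilon"]))


def init_params(layout: VisibleLayout, n_hidden: int, seed: int = 0,
                w_scale: float = 0.01) -> CRBMParams:
    """Small random weights, zero biases, unit scales."""
    rng = np.random.default_rng(seed)
    n_vis = layout.n_cols
    return CRBMParams(layout, rng.normal(0.0, w_scale, size=(n_vis, n_hidden)),
                      np.zeros(n_vis), np.zeros(n_hidden),
                      np.ones(n_vis), np.ones(n_hidden))


# ---------------------------------------------------------------------------
# Energy and conditionals
# ---------------------------------------------------------------------------

def _check_v(v: np.ndarray, params: CRBMParams) -> np.ndarray:
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if v.shape[1] != params.n_visible:
        raise ValueError(f"visible dimension {v.shape[1]} != {params.n_visible}")
    return v


def energy(v: np.ndarray, h: np.ndarray, params: CRBMParams) -> np.ndarray:
    """Energy E(v, h); p(v, h) is proportional to exp(-E)."""
    v = _check_v(v, params)
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if h.shape[1] != params.n_hidden:
        raise ValueError(f"hidden dimension {h.shape[1]} != {params.n_hidden}")
    if np.any(h < 0):
        raise ValueError("hidden values must be >= 0")
    lay, sig, eps = params.layout, params.sigma, params.epsilon
    a = np.zeros(v.shape[0])
    g = lay.gaussian_cols
    if len(g):
        a += -np.sum((v[:, g] - params.vis_bias[g]) ** 2 / (2.0 * sig[g] ** 2), axis=1)
    lin = np.concatenate([lay.binary_cols] + [grp for grp in lay.onehot_groups]) \
        if (len(lay.binary_cols) or lay.onehot_groups) else np.array([], dtype=int)
    if len(lin):
        a += v[:, lin] @ params.vis_bias[lin]
    b = -np.sum((h - params.hid_loc) ** 2 / (2.0 * eps ** 2), axis=1)
    interaction = np.sum(((v / sig ** 2) @ params.W) * (h / eps ** 2), axis=1)
    return -(a + b + interaction)


def hidden_conditional(v: np.ndarray, params: CRBMParams) -> tuple[np.ndarray, np.ndarray]:
    """Underlying (mean, sd) of the zero-truncated normal h | v, per unit."""
    v = _check_v(v, params)
    m = params.hid_loc + (v / params.sigma ** 2) @ params.W
    return m, np.broadcast_to(params.epsilon, m.shape)


def truncated_normal_mean(m: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """E[h] for h ~ Normal(m, eps) truncated below at zero."""
    alpha = m / eps
    log_ratio = -0.5 * alpha ** 2 - 0.5 * np.log(2.0 * np.pi) - special.log_ndtr(alpha)
    return m + eps * np.exp(log_ratio)


def hidden_mean(v: np.ndarray, params: CRBMParams) -> np.ndarray:
    """Conditional mean E[h | v] (Rao-Blackwellized hidden activation)."""
    m, eps = hidden_conditional(v, params)
    return truncated_normal_mean(m, eps)


def sample_hidden(v: np.ndarray, params: CRBMParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw h | v from the per-unit zero-truncated normals."""
    m, eps = hidden_conditional(v, params)
    a = -m / eps  # lower bound in standard units; robust in far tails
    return truncnorm.rvs(a=a, b=np.inf, loc=m, scale=eps, size=m.shape,
                         random_state=rng)


def visible_conditional(h: np.ndarray, params: CRBMParams) -> dict:
    """Distribution spec of v | h, per unit group.

    Returns a dict with gaussian means/sds, Bernoulli probabilities, and
    per-group categorical probabilities, keyed by layout columns.
    """
    h = np.atleast_2d(np.asarray(h, dtype=float))
    J = (h / params.epsilon ** 2) @ params.W.T           # (B, n_vis)
    lay, sig, c = params.layout, params.sigma, params.vis_bias
    spec: dict = {"gaussian_cols": lay.gaussian_cols, "binary_cols": lay.binary_cols,
                  "onehot_groups": lay.onehot_groups}
    g = lay.gaussian_cols
    spec["gaussian_mean"] = c[g] + J[:, g] if len(g) else np.zeros((h.shape[0], 0))
    spec["gaussian_sd"] = sig[g]
    b = lay.binary_cols
    spec["binary_p"] = special.expit(c[b] + J[:, b] / sig[b] ** 2) \
        if len(b) else np.zeros((h.shape[0], 0))
    probs = []
    for grp in lay.onehot_groups:
        logits = c[grp] + J[:, grp] / sig[grp] ** 2
        probs.append(special.softmax(logits, axis=1))
    spec["onehot_p"] = probs
    return spec


def sample_visible(h: np.ndarray, params: CRBMParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw v | h; one-hot groups come back with exactly one active level."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    spec = visible_conditional(h, params)
    B = h.shape[0]
    v = np.zeros((B, params.n_visible))
    g = spec["gaussian_cols"]
    if len(g):
        v[:, g] = rng.normal(spec["gaussian_mean"], spec["gaussian_sd"])
    b = spec["binary_cols"]
    if len(b):
        v[:, b] = (rng.random(size=(B, len(b))) < spec["binary_p"]).astype(float)
    for grp, p in zip(spec["onehot_groups"], spec["onehot_p"]):
        cum = np.cumsum(p, axis=1)
        u = rng.random(size=(B, 1))
        idx = (u > cum[:, :-1]).sum(axis=1)
        onehot = np.zeros((B, len(grp)))
        onehot[np.arange(B), idx] = 1.0
        v[:, grp] = onehot
    return v


def sample_bias_only(params: CRBMParams, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw visible vectors from the no-interaction (bias-only) distribution.

    Used to initialize free units of a Gibbs chain without looking at data.
    """
    zero_h = np.zeros((n, params.n_hidden))
    p = params.copy()
    p.W = np.zeros_like(p.W)
    return sample_visible(zero_h, p, rng)


def gibbs_sample(v0: np.ndarray, clamp_mask: np.ndarray | None,
                 params: CRBMParams, n_steps: int,
                 rng: np.random.Generator,
                 return_hidden: bool = False):
    """Alternate hidden/visible sampling, resampling only unclamped units.

    Parameters
    ----------
    v0 : (B, n_vis) array
        Starting visible vectors; clamped coordinates must hold their values.
    clamp_mask : bool array (n_vis,) or (B, n_vis), or None
        True entries are held fixed across all steps.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    v = _check_v(v0, params).copy()
    if clamp_mask is None:
        clamp = np.zeros(v.shape, dtype=bool)
    else:
        clamp = np.broadcast_to(np.asarray(clamp_mask, dtype=bool), v.shape)
    h = None
    for _ in range(n_steps):
        h = sample_hidden(v, params, rng)
        v_new = sample_visible(h, params, rng)
        v = np.where(clamp, v, v_new)
    return (v, h) if return_hidden else v


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_visible_states(layout: VisibleLayout, limit: int = 4096) -> np.ndarray:
    """All visible states of an all-binary/one-hot layout (rows)."""
    per_group: list[np.ndarray] = []
    for g in layout.groups:
        if g.kind == "binary":
            per_group.append(np.array([[0.0], [1.0]]))
        elif g.kind == "onehot":
            per_group.append(np.eye(len(g.cols)))
        else:
            raise ValueError("exact enumeration requires binary/one-hot units only")
    total = int(np.prod([s.shape[0] for s in per_group]))
    if total > limit:
        raise ValueError(f"{total} visible states exceed the enumeration limit {limit}")
    states = np.zeros((total, layout.n_cols))
    reps = total
    tile = 1
    for g, block in zip(layout.groups, per_group):
        k = block.shape[0]
        reps //= k
        idx = np.tile(np.repeat(np.arange(k), reps), tile)
        states[:, np.array(g.cols)] = block[idx]
        tile *= k
    return states


def log_unnormalized_marginal(v: np.ndarray, params: CRBMParams) -> np.ndarray:
    """log of the h-integrated unnormalized density at visible states v.

    Each hidden unit contributes a closed-form Gaussian tail factor
    sqrt(2 pi) eps * exp((m^2 - theta^2) / (2 eps^2)) * Phi(m / eps)
    with m = theta + sum_j W_{j mu} v_j / sigma_j^2.
    """
    v = _check_v(v, params)
    lay, c = params.layout, params.vis_bias
    lin = np.concatenate([lay.binary_cols] + list(lay.onehot_groups)) \
        if (len(lay.binary_cols) or lay.onehot_groups) else np.array([], dtype=int)
    a = v[:, lin] @ c[lin] if len(lin) else np.zeros(v.shape[0])
    g = lay.gaussian_cols
    if len(g):
        a += -np.sum((v[:, g] - c[g]) ** 2 / (2.0 * params.sigma[g] ** 2), axis=1)
    m = params.hid_loc + (v / params.sigma ** 2) @ params.W     # (B, n_hid)
    eps = params.epsilon
    logF = ((m ** 2 - params.hid_loc ** 2) / (2.0 * eps ** 2)
            + np.log(_SQRT_2PI * eps) + special.log_ndtr(m / eps))
    return a + logF.sum(axis=1)


def exact_marginal(params: CRBMParams) -> tuple[np.ndarray, np.ndarray]:
    """Exact marginal p(v) over all enumerable visible states.

    Returns (states, probabilities); probabilities sum to one. Requires an
    all-binary/one-hot visible layer with at most 4096 states.
    """
    states = enumerate_visible_states(params.layout)
    logp = log_unnormalized_marginal(states, params)
    logp -= special.logsumexp(logp)
    return states, np.exp(logp)


def exact_visible_moments(params: CRBMParams) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean vector and covariance of v under the enumerated marginal."""
    states, p = exact_marginal(params)
    mean = p @ states
    centered = states - mean
    cov = (centered * p[:, None]).T @ centered
    return mean, cov
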