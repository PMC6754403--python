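# Methods

## Model

The package models a longitudinal cohort with a conditional restricted
Boltzmann machine: a bipartite energy model whose visible layer is the
concatenation `v = [x_dyn(t), x_dyn(t−1), x_static]` of the dynamic
variables at two neighboring visits and the static baseline covariates,
and whose hidden layer is a vector of rectified latent units. The joint
density is

    p(v, h) ∝ exp( Σ_j a_j(v_j) + Σ_μ b_μ(h_μ)
                   + Σ_{jμ} W_{jμ} (v_j/σ_j²)(h_μ/ε_μ²) ),   h_μ ≥ 0.

The per-unit terms are the canonical exponential-family forms compatible
with the bilinear interaction:

* binary and one-hot columns: linear, `a_j(v) = c_j v`;
* continuous (and encoded-ordinal) columns: quadratic location–scale,
  `a_j(v) = −(v − ν_j)²/(2σ_j²)`;
* hidden units: quadratic truncated at zero,
  `b_μ(h) = −(h − θ_μ)²/(2ε_μ²)` on `h ≥ 0` (a normal lower-truncated at
  zero; the "ReLU" unit of the machine-learning literature).

These choices give closed-form layer conditionals: `h_μ | v` is a
zero-truncated normal with underlying mean `θ_μ + Σ_j W_{jμ} v_j/σ_j²` and
scale `ε_μ`; continuous `v_j | h` is normal with mean `ν_j + J_j`
(`J_j = Σ_μ W_{jμ} h_μ/ε_μ²`) and scale `σ_j`; binary units are Bernoulli
with log-odds `c_j + J_j/σ_j²`; one-hot groups are categorical through a
softmax of their levels' affine inputs. The scales `σ_j`, `ε_μ` are kept
fixed at 1 (columns are standardized before modelling), so the learned
quantities are `W`, the visible bias parameters, and the hidden locations.

Because every neighboring-visit pair is pooled into one training set, a
single model describes all transitions; a trajectory is simulated by
clamping `[x_dyn(t−1), x_static]` and Gibbs-sampling the `t` slab, then
advancing. One time-lagged connection is assumed sufficient for the
3-month visit grid.

For models whose visible layer is entirely binary/one-hot, the hidden
layer integrates out in closed form — each hidden unit contributes a
factor `√(2π) ε exp((m²−θ²)/(2ε²)) Φ(m/ε)` with `m = θ + Σ_j W_j v_j/σ_j²`
— so the exact marginal over at most 4096 enumerable visible states is
available. This enumeration oracle (cross-checked against adaptive
quadrature of the h-integral) validates the Gibbs sampler and training
end to end.

## Encoding

Categorical variables are one-hot encoded; positive continuous variables
are log-transformed and z-standardized; other continuous variables are
z-standardized. Ordinals (the ADAS/MMSE components, with up to 13 levels)
are kept as standardized integer columns and decoded by rounding and
clipping to their bounds — one-hot ordinals would multiply the visible
dimension several-fold for no clear gain. Standardization statistics are
frozen from the training patients and reused for validation, test, and
synthetic data. Missing cells are masked, never filled, at encoding time.

## Training

Fitting is stochastic maximum likelihood: the gradient is the data-phase
minus model-phase expectation of the sufficient statistics, with the model
phase estimated from persistent Gibbs chains (default 100) advanced a few
steps per update. Hidden activations are Rao-Blackwellized (the truncated-
normal conditional mean replaces a sample) in both phases. Rows with
missing coordinates are imputed at the start of every gradient step by
drawing from `p(v_missing | v_observed)` under the current parameters
(5 Gibbs refresh steps); observed coordinates are never overwritten.

The optional adversarial penalty keeps a linear critic on hidden
activations, refit every few minibatches to the direction separating
data-phase from model-phase batches, and penalizes the squared gap between
mean critic scores; its gradient with respect to the parameters is the
covariance, over the chains, of the critic score with the sufficient
statistics. This is a deliberately simple distinguishability penalty with
weight λ (default 0.1); λ = 0 is exact pure-SML mode and is what all
calibration studies use.

Defaults: learning rate 5e-3 with geometric per-epoch decay 0.98,
minibatch 128, weight init N(0, 0.01²), biases initialized from the
training marginals, hidden locations at zero. `TrainConfig.average_from`
enables tail (Polyak) averaging of the parameters over the final epochs,
which substantially reduces stochastic-gradient noise; the parameter-
recovery study uses it together with a larger initial rate (0.25), because
near `W = 0` the likelihood has a saddle whose escape rate scales with the
learning rate and the small default stalls at toy scale.

Cross-validation follows a patient-level 5-fold plan: per fold ~20% test,
~5% validation, ~75% training, every patient in exactly one test set,
splits by patient and never by visit. The validation score is a
pseudo-likelihood surrogate: the mean per-coordinate log-density of
observed cells under single-unit conditionals given the Rao-Blackwellized
hidden activation.

## Simulation

Type-i trajectories condition on real baselines: missing baseline cells
are imputed once by conditional sampling and held fixed across replicates;
observed baseline cells are reproduced exactly in the output. Each
transition is one conditional draw via 20 Gibbs steps (configurable) with
the previous visit and statics clamped and free units initialized from
their bias-only distributions — the identical kernel is used for "observed"
reference-model data and for replicates, so calibration comparisons are
exact by symmetry rather than dependent on perfect chain convergence.
Type-ii (de novo) patients draw statics and the baseline slab jointly by
500 steps of unclamped Gibbs on the full concatenated vector, then proceed
as type i. Sampled dropout is absorbing: visits after the first dropout
event are flagged `post_dropout` and can be excluded downstream.

Per-patient conditional means and variances (the minimum-MSE forecast and
its uncertainty) are Monte-Carlo estimates over replicates, on decoded
variable scales.

## Evaluation battery

* **z-scores** `z_ij(t) = (x_ij(t) − E[x_ij(t)|x_i(0)])/√Var[x_ij(t)|x_i(0)]`,
  pooled across patients per (variable, visit). The KS statistic compares
  the fitted normal N(μ̂, σ̂) with N(0, 1) by dense-grid supremum; p-values
  come from the asymptotic Kolmogorov distribution at √n·D with no
  finite-n correction; Bonferroni uses all tested cells of a report as the
  family. Cells with vanishing conditional variance are excluded and
  counted.
* **Correlations** are Pearson over complete pairs only (equal-time per
  visit; lags of 3 or 6 months across visits), each with the fraction of
  complete pairs as its weight; observed-vs-simulated agreement is the R²
  of a weighted least-squares fit. Fewer than 3 complete pairs → the pair
  is reported unavailable.
* **Distinguishability AUC**: per repeat, one synthetic replicate per
  patient; the real records' missing cells are mean-imputed and the same
  values copied into the paired synthetic records so missingness carries
  no class signal; a logistic regression is scored by pooled out-of-fold
  decision values under 5-fold CV *grouped by patient*. Grouping matters:
  fold-splitting that separates a patient's real and synthetic rows lets
  the classifier recognize memorized training rows in the test fold and
  biases the null AUC well below 0.5.
* **Forecasting**: RMSE scaled by the population (divide-by-n) sd of the
  observed targets, so predicting the mean scores exactly 1; rows with a
  missing target are excluded for model and comparator alike. The
  comparator is a per-(variable, visit) supervised learner on mean-imputed
  baseline features (200-tree random forest by default, linear optional).
* **Covariance diagnostics**: pairwise covariances from data, from model
  samples, and from deterministic comparator predictions, with Theil–Sen
  (median-of-pairwise-slopes) regression of each against the data. By the
  law of total variance the deterministic conditional-mean predictor lacks
  exactly the expected-conditional-covariance term, which is why its
  covariances undershoot.
* **ADAS-Cog11** is the sum of the 11 constituent ADAS components
  (delayed word recall tracked but excluded); the total is missing if any
  component is. Fast/slow progressors are the top/bottom 5% by 18-month
  change in this total; baseline separations are absolute Cohen's d with
  the (n−1)-weighted pooled sample sd.

## Synthetic cohort generator

The generator draws a latent Gaussian vector per patient per visit from a
block-correlation matrix (within-category ρ_in = 0.4, between-category
ρ_out = 0.05 by default — the categories correlate strongly internally and
only weakly across), evolves it as an AR(1) with coefficient 0.7 across
visits, and maps it through each variable's marginal: exact lognormal
moment matching for positive continuous variables, exact frequencies for
binary/categorical, and a discretized-normal fit (location/scale solved so
the discrete mean and sd hit the schema targets) for ordinals. Cognitive
variables drift on the latent scale by 0.12 per visit (ADAS upward, MMSE
downward), a 20% progressor subpopulation drifts 3× faster — producing a
rising ADAS-Cog11 mean with a widening right tail — dropout is an
absorbing per-visit hazard (default 0.05) after which all dynamic values
are missing, and per-variable missingness is injected at the schema's
baseline rates (including the 72.4% ApoE rate, which stress-tests
imputation). Defaults for quantities no source documents (ρ's, drift,
progressor fraction, AR coefficient, hazard) were chosen once as
clinically plausible and are configuration, not constants.

What the generator does *not* emulate: the real repository's exact joint
distribution, informative (non-random) missingness beyond dropout,
visit-schedule irregularity, and site or trial heterogeneity. Passing
tests on generated cohorts therefore demonstrate the pipeline's internal
correctness and calibration, not real-data fidelity.

## Calibration studies and their scales

Self-contained studies in `trajgen.calibration` use a small reference CRBM
(5 continuous dynamic variables, 2 statics, 3 hidden units, weights scaled
to spectral norm 0.6 so the h-integrated Gaussian layer stays proper) as
ground truth:

* **z-calibration** — 300 patients, 100 conditional replicates each, all
  dynamic variables and 6 visits pooled (9000 z-values). Standard errors
  are patient-clustered (one patient's z-values share a baseline and
  moment estimates). Estimating moments from R replicates inflates E[z²]
  by (1+1/R)(R−1)/(R−3) under normality (~1.5% in sd at R = 100); the
  study reports the raw and the debiased sd, whose ideal value is exactly
  one.
* **AUC null** — the same protocol as the distinguishability test, 300
  patients, 20 repeats with fresh synthetic draws, averaged over the six
  post-baseline visits.
* **parameter recovery** — 5000 vectors sampled from a fixed enumerable
  6-binary/2-hidden generator, fitted at λ = 0; the fitted model's exact
  means and pairwise correlations are compared with the training sample's
  (the generator's Monte-Carlo estimate) in units of the sample's standard
  errors, and KL(generator‖fit) is verified to drop from initialization.
* **variance decomposition** — a two-level Gaussian generator
  (x(t)|x(0) ~ N(Ax(0), S), 60 000 samples) checks the covariance identity
  and that a deterministic conditional-mean predictor's covariance deficit
  equals S.

These sizes keep the full battery to a few minutes on one CPU while
leaving the stated 3-standard-error tolerances well resolved.

## Numerical choices and degenerate inputs

Truncated-normal sampling uses scipy's inverse-CDF/tail-robust sampler, so
far-tail locations do not underflow; the truncated-normal mean is computed
through `log Φ` for stability. Visit-window assignment uses half-open
windows `(center − 45, center + 45]` days (the left edge of the month-0
window closed), so a record exactly 45 days past a center belongs to that
center and no record lands in two windows. One-hot decoding takes the
argmax; ordinal decoding rounds then clips. Zero-variance cells are
excluded from z-scores, zero observation sd makes scaled RMSE an error,
zero pooled sd makes an effect size unavailable (NaN), and degenerate
correlation pairs (constant series or < 3 complete pairs) are reported
unavailable rather than fabricated. All randomness flows through seeded
`numpy` generators; fits, simulations, and studies are bit-reproducible
from their seeds.

## Known limitations

The adversarial term is a documented simplified variant (linear critic on
hidden activations), not a reproduction of any specific published
adversarial objective. Scales σ and ε are fixed rather than learned.
Real-data headline numbers cannot be reproduced here because the
motivating repository is access-restricted; the acceptance surface is
calibration against reference models. The CLI covers the standard
workflow; hyperparameter search beyond the validation-score hook, GPU
training, and horizons beyond 18 months are out of scope.
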