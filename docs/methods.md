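# Methods

## Scope

`vitalcast` forecasts five ICU vital-sign trajectories jointly, 25 steps
(6.25 h at 15-minute bins) ahead from 75 steps (18.75 h) of history, at
the 10th/50th/90th quantiles, with a loss and metrics that see only
genuinely observed values. This note records the modelling assumptions,
the parameter choices that matter, what the synthetic cohort does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Data preparation

Irregular long-format observations (subject, timestamp, variable, value)
are aggregated onto left-closed 15-minute bins `[t, t+15)` anchored at
each subject's first observation: within-bin mean for numeric variables,
within-bin median for categorical ones (a tied median of 0.5 on a binary
variable rounds half up — intent of "median" for even counts is
ambiguous; rounding half up keeps the output binary). Empty bins are
forward-filled; a leading gap takes the variable's training-subject mean
of real values, which keeps inputs finite without leaking future or
test-set information. The per-bin mask (1 = bin held ≥1 raw observation)
is carried unchanged through filling; it is the single source of truth
for "real value" everywhere downstream.

All pressor administrations collapse into one binary medication channel;
absence of a record means no medication, so this channel is
fill-with-zero, never forward-filled. Binary static covariates impute
missing as 0; subjects missing a numeric static covariate are dropped
and reported. Continuous inputs are z-scored per variable using training
subjects' real values only; binary channels pass through and are embedded
by the model. A deterministic elapsed-time channel (`hours_in`) serves as
the known-future covariate — the synthetic stand-in for age in a clinical
schema, where it is also appended to the past inputs.

Each encounter contributes one window anchored at its first 100 bins
(encounters shorter than 100 bins are dropped and counted; anchoring at
the start is the deterministic choice, and sliding windows were left out
to keep one window per encounter). Splits are by subject, never by
window, at an 80/20 ratio.

## Architecture

The network is a temporal fusion transformer: per-variable linear
projections (learned 2-row embeddings for binary channels) to a common
`state_size`; a static covariate encoder producing four context vectors
(selection, LSTM initial state ×2, enrichment); variable-selection
networks (per-variable gated residual networks plus a softmax selection
GRN, conditioned on the static selection context) over static, past and
future inputs; an LSTM encoder over the past and decoder over the future
(decoder initialised from the encoder's final state) with a gated
residual skip; static enrichment; interpretable multi-head attention
(per-head queries/keys, one shared value projection, head-averaged
output) in which future position *i* attends to all past positions and
future positions ≤ *i*; a position-wise GRN; and a single dense head
mapping each future step to `n_targets × n_quantiles` values.

A selection network over a single variable would have a constant softmax
weight of 1, so for one-variable groups the selection GRN is not built
(avoiding a parameter branch that can never receive gradient).

Targets are modelled on the z-scored scale — the pinball losses of five
channels with clinical magnitudes from ~0.4 (temperature sd) to ~10
(pulse sd) would otherwise be dominated by the wide channels — and
predictions are mapped back to clinical units at inference. Quantile
ordering is unconstrained during training (the plain quantile-loss
objective); at inference the quantile axis is sorted non-decreasing per
(step, target) so the 10–90 band is always a valid interval.

Reference hyperparameters: state size 240, 2 attention heads, dropout
0.3, Adam at learning rate 1e-3, batch 800, up to 2000 epochs with early
stopping. Fixture scale (used throughout the tests and the acceptance
script so a full study runs in minutes on one CPU): state size 16,
dropout 0.1, batch 32, 30 epochs (20 for scenario models), 375-subject
cohorts (240 for scenario studies). Dropout is reduced at fixture scale
because a 16-unit state under 0.3 dropout loses too much capacity to
converge in a short budget; all other optimiser settings keep the
reference values.

## Loss and training

The masked multivariate pinball loss sums, over target variables and
quantiles, the per-window pinball losses averaged over that window's
*real* future steps of that variable, then averages over windows. A
(window, variable) pair with no real future step would have a zero
denominator; its term is defined as 0 (skipped) rather than NaN, keeping
the estimator finite and weighted toward observed variables.

Training uses Adam with global gradient-norm clipping at 1.0 (standard
stabilisation for recurrent-attention hybrids), per-epoch shuffling under
the run seed, and a validation split of 10% of training *subjects*.
"Early stopping after the loss rises continuously for 20 epochs" is read
as 20 consecutive epochs each worse than the previous; the
best-validation checkpoint is restored at the end. The split is carved
from training subjects so the stopping rule never sees test data.

## The numerical core

The network, gradients and optimiser run on a small reverse-mode
autodiff engine over NumPy (`vitalcast.nn`): a `Tensor` graph with fused
operations (LSTM cell, layer normalisation, softmax, linear) to keep the
per-timestep Python overhead low. Everything is float64 and
single-threaded, so training is bit-reproducible under a fixed seed on
any machine. Analytic gradients are verified against central finite
differences to ~1e-10 in the test suite. This is deliberately a minimal
engine, not a framework: only the operations the architecture needs
exist.

## The synthetic cohort

The generator emulates the *structure* that matters to the method, with
everything known in closed form:

* per-channel standardized deviations follow a stationary AR(1) with
  coefficient 0.9 (strong persistence, as vitals have at 15-minute
  resolution) and unit marginal variance;
* SpO2's deviation is 0.8 × the previous bin's pulse deviation plus an
  independent innovation — the cross-channel signal a joint model should
  exploit;
* clinical scales: means (75, 85, 97, 18, 37) and sds (8, 10, 2, 4, 0.4)
  for mean BP / pulse / SpO2 / resp / temp, roughly ICU-typical;
* mean BP gains +5 mmHg while a pressor is active (a contiguous interval
  of 10–40 bins in ~50% of subjects) and +3 mmHg if the first static
  flag is set;
* observations add measurement noise (25% of the channel sd) and are
  dropped missing-completely-at-random at per-channel rates
  (0.15, 0.05, 0.70, 0.30, 0.60) — SpO2 at 70% is the
  high-missingness channel of interest;
* timestamps sit on the 15-minute grid with ±5 minutes of uniform
  jitter, so the resampler does real aggregation.

`truth_forecast` propagates the AR(1)/coupled conditional means from the
latent state at the forecast origin — an exact oracle no model trained on
the same information can systematically beat.

What the cohort does *not* emulate — and therefore what passing tests do
not show about real data: informative (disease-severity-driven)
missingness, alarm artifacts and sensor dropouts, nonstationary
dynamics, dose-varying medication response, lab covariates, and
inter-channel couplings beyond the single injected one. Results on this
cohort validate the machinery (masking, joint modelling, scenario
plumbing), not clinical performance.

## Evaluation conventions

* Masked MAE pools |y−ŷ| over all real points per target; a target with
  no real points is reported undefined (NaN), never 0.
* Masked MAPE is the mean of per-point ratios (not a ratio of sums);
  zero-truth points are excluded and counted.
* Coverage uses the closed interval [q10, q90]; ties on the bound are
  counted covered (measure-zero in continuous data). Per-subject
  percentages are summarised by quartiles with linear interpolation.
* Bland–Altman limits are mean ± 1.96 × sample sd (ddof = 1) of
  prediction − truth differences over real points.
* The lookback ablation reuses the full windows, truncating the past to
  the last 12 / 36 / 75 bins (3 / 9 / 18.75 h) and retraining from
  scratch with the same seed.

## Interpretability

Per-feature importance is computed from the variable-selection softmax
weights, averaged over steps then windows and renormalised per input
group; temporal attention weights are a *positional* quantity and are
reported separately as a horizon-by-position profile rather than folded
into the feature ranking. Both tensors are exposed on every forecast so
either aggregation can be computed. Importance is aggregated over all
test windows and steps; it is a population-level summary and is not
informative at the single-subject level.

## Scenario analysis

A separate model is trained with medication as a known-future input.
For treated test subjects, each window is re-forecast under the observed
schedule, all-ones, and all-zeros; only the medication block differs, so
forecast differences isolate the learned medication response. The
comparison between counterfactuals is reported two ways — an
unequal-variance two-sample test pooling per-step predictions, and a
paired-by-step test — because the pooling/pairing choice is a genuine
degree of freedom; both are labelled in the output. Tests are run over
all steps and separately over steps where medication was / was not
actually given (a disjoint, exhaustive partition); a partition cell with
fewer than two steps is flagged not-computable rather than guessed.

## Known limitations

* Fixture-scale training (state 16, tens of epochs) underestimates the
  medication effect (≈2–3.5 mmHg recovered of the injected 5) — direction
  and significance are robust, magnitude is not converged.
* MCAR missingness is an assumption of the fixture, not of clinical
  data; the masked loss is agnostic, but recovery results would differ
  under informative missingness.
* One window per encounter discards later data in long encounters;
  sliding windows would increase sample efficiency at the cost of
  within-subject dependence between windows.
* The quantile head is sorted, not jointly constrained; crossing in the
  raw outputs is possible (and observed early in training).
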