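# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of `gaitmet`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The regression problem

Each walking trial is represented by five stride-averaged waveforms on a
common 100-point gait-cycle grid `t_i = (i−1)/99`, `i = 1..100`
(heel-strike at 0 %, next ipsilateral heel-strike at 100 %): vertical and
anterior–posterior GRF in N/kg and hip/knee/ankle sagittal moments in
N·m/kg, all mass-normalized. The target is one scalar per trial, the net
metabolic rate in W/kg. Raw series of any length and sample rate are
mapped to the grid by linear interpolation (`resample_to_gait_cycle`);
linear rather than spline interpolation because it is monotone,
artifact-free, and exact on ramps. Resampling is idempotent and commutes
with affine transforms, both enforced by property tests.

Trials are split 70/15/15 into train/validation/test by a seeded shuffle
with the *ceiling rule*: `|val| = ceil(0.15·N)`, `|test| = ceil(0.15·N)`,
train takes the remainder — for N = 270 this yields 188/41/41. The split
is trial-level, not participant-level: trials of one participant may
appear in both train and test. This mirrors a flat random split of a
repeated-measures cohort and is a **known leakage caveat**; an optional
stratification flag groups the split by a label (e.g. study) but there is
deliberately no subject-wise grouping.

## NARX model and training

The network is a single-hidden-layer NARX regressor. With `d` input
delays, `q` feedback delays (default `q = d`) and `C` channels, the
regressor row at step `t` holds the current and `d` delayed values of
each channel plus `q` delayed targets — `C(d+1)+q` inputs — feeding a
tanh hidden layer of size `H` and a linear output. Weights flatten in the
fixed order `W_in` (row-major), `b_hidden`, `W_out`, `b_out`.

Inputs and the target are z-scored with training-set statistics
(per-channel pooled over time); predictions are de-standardized. Without
this, tanh units saturate on raw forces (~10 N/kg).

**Scalar-target bridge.** The calorimetry target is one number per trial,
but a NARX network predicts a series. The scalar is replicated across all
100 steps to form the training target series; the trial-level prediction
closes the loop (feedback taps filled with the model's own previous
outputs, seeded at the training-set mean target) and averages the
per-step outputs over the post-warm-up steps.

**Feedback dither.** With a replicated constant target, the open-loop
feedback tap *equals* the target, so an unregularized optimizer can reach
zero training error by copying the tap — a solution whose closed-loop
prediction is the same for every trial and therefore useless. Training
therefore adds seeded Gaussian dither (default sd 0.1 in standardized
target units, `NarxConfig.feedback_dither`) to the feedback columns of
the pooled regressor matrices. Dither makes feedback weights cost what
they are worth: the network keeps a (contracting) feedback pathway for
temporal smoothing but routes trial identity through the exogenous
channels, and the closed-loop pass converges to a trial-specific value.
0.1 was chosen as the smallest level that reliably breaks the copy
solution while leaving the feedback pathway useful; it is a tunable of
the method, set once, and `feedback_dither=0` recovers textbook
series–parallel training.

**Optimizer.** Full-batch Levenberg–Marquardt on the pooled regressor
matrix of all training trials. Per epoch: compute the residual Jacobian
`J = ∂e/∂w` analytically (verified against central finite differences to
relative error < 1e-5), solve `(JᵀJ + μI)δ = Jᵀe`, propose `w − δ`;
accept and shrink `μ` by 0.1 if the SSE decreases, otherwise reject and
grow `μ` by 10 within the same epoch. Training stops at `max_epochs`
(default 1000), when `μ` exceeds 1e10, or after 6 consecutive epochs
without a new validation minimum; the returned weights are those of the
best validation epoch. `μ` starts at 0.001 — the damping initialization
conventionally paired with this optimizer; a nominal "learning rate" has
no meaning in LM. LM is inherently full-batch, so a batch size does not
apply to the default trainer; a literal mini-batch gradient trainer
(batch 15, step 0.001) is available via `NarxConfig(trainer="sgd")` for
anyone wanting that reading. Weights initialize uniform(−0.5, 0.5) under
the config seed; all training is bit-reproducible from config + data.

**History units.** Per-epoch (train, validation) MSE is recorded in
physical (W/kg)² so curves are comparable across targets. Validation MSE
is per-step on the pooled (dithered) validation matrix.

## Architecture search and cross-validation

`grid_search` enumerates (hidden size, delays, repetition) cells — the
full sweep spans hidden 2–50, delays 1–4, 1000 reiterations per cell;
ranges and repetition count are arguments so the same loop runs at desk
scale (the CLI default is 25 repetitions). Repetition seeds are
`base_seed + repetition index`. Each cell records trial-level
(closed-loop) MSE and Pearson R per partition; the winner is the exact
argmin of validation MSE, ties broken toward fewer hidden units, then
fewer delays, then the lower repetition index. `grid_search_series` is
the same loop for genuinely time-varying targets, scored by per-step
open-loop MSE — this variant is what demonstrates delay selection:
on series with `y(t) = 0.5x(t) + 1.2x(t−2)`, delay ≥ 2 wins the grid.

`kfold_cv` (k = 5 by default) shuffles trials into near-equal folds (270
trials → five folds of 54); each fold is scored by a model trained on the
remainder with an internal 85/15 early-stopping carve-out; reported as
mean ± sd of fold MSE and R.

Where a single representative model matters (the acceptance script's
recovery and sensitivity stages, the stochastic recovery tests), three
re-initializations are trained and the one with the lowest validation MSE
kept — the sweep's reiteration strategy at reduced count, which removes
occasional poor local optima.

## Synthetic cohort generator

No public dataset of paired stride-averaged waveforms and calorimetry
exists for this design, so the generator is a first-class, tested module
that fabricates cohorts with known ground truth.

**Layout.** Two studies — footwear (10 participants × 15 conditions) and
exoskeleton (10 participants × 12 conditions), 270 trials — at a fixed
1.25 m/s. Stance occupies the first 60 % of the cycle by default
(admissible range 0.4–0.8).

**Waveform templates** (raised cosine
`rc(x; c, w) = 0.5(1 + cos(2π(x−c)/w))` on `|x−c| ≤ w/2`, else 0):

* vertical GRF: two bumps in normalized stance time `s = t/0.6`, centres
  0.30 and 0.72, width 0.62, peak amplitudes ~10.5 and ~10.0 N/kg — the
  canonical double hump with a mid-stance valley; zero over swing,
  non-negative everywhere by construction;
* AP GRF: one sine period over stance, amplitude ~1.8 N/kg, braking
  before mid-stance and propulsion after, mean-centred over stance so the
  discrete net impulse over the cycle is exactly zero (steady speed);
* joint moments: sums of ≤ 4 signed raised cosines with per-joint centres
  and widths (`MOMENT_COMPONENTS`); the ankle has a sharp plantarflexion
  peak at 45 % (push-off), a gentler mid-stance rise and a small early
  dorsiflexion dip, with default peak ~1.5 N·m/kg; hip ~1.0, knee
  ~0.7 N·m/kg. Amplitude values sit at textbook magnitudes for walking at
  this speed.

**Heterogeneity.** One latent gait-intensity factor per participant and
one per condition, drawn standard-normal once per unit and reused across
that unit's trials; each channel responds with its own sensitivity (the
per-channel sds, defaults 0.08 participant / 0.10 condition), entering as
log-normal multiplicative amplitude factors. Multiplicative rather than
additive effects preserve the swing-zero and non-negativity invariants at
every seed; the shared latent factor reproduces the cross-channel
coupling of repeated-measures gait data (a vigorous participant scales
forces and moments together) and makes the cost recoverable from the GRF
channels alone. Per-channel measurement noise (default sd 0.03, trial
level, independent across channels) enters the same way.

**Generative cost law.** `met_cost = c0 + w·f + ε` with
`c0 = 1.0 W/kg`, `ε ~ N(0, 0.10²)` W/kg (calorimetry repeatability
stand-in), and features

```
f1 = mean_i max(grf_ap_i, 0)        positive AP (propulsive) impulse
f2 = mean_i |ankle_m_i|             ankle moment magnitude
f3 = mean_i (|hip_m_i| + |knee_m_i|)
f4 = max_i grf_ver_i                vertical GRF peak
```

with weights `w = (2.0, 2.5, 1.0, 0.08)`, chosen so the default cohort
spans ≈3–5 W/kg — the plausible range for level walking at 1.25 m/s —
with each feature contributing a non-trivial share. Linearity makes
recovery provable: tests recompute the law with an independent
brute-force implementation to 1e-12.

`pushoff_ankle_cohort` is a deliberately degenerate companion design for
phase-attribution checks: every waveform is fixed except the ankle
push-off bump amplitude (log-normal, sd 0.15), and the cost weights only
`f2`. Because the sole across-trial signal lives in the 40–60 % window, a
correct sensitivity analysis must put its RMSE peak there. (In the full
cohort the shared intensity factor makes cost readable from any
percentage, so peak location is not identifiable there — by design, not
by accident.)

**What the generator does not emulate:** waveform *shape* variation
(timing shifts, condition-specific profiles), left/right asymmetry
(single-limb waveforms, symmetric by assumption), breath-by-breath
calorimetry dynamics, non-steady speeds. Passing tests therefore show
that the pipeline recovers a known smooth amplitude-coded mapping under
realistic noise — not that real metabolic cost is predictable to the same
accuracy; the published experiments are the evidence for that.

## Perturbation sensitivity (PDP)

For a trained model and one channel: for each gait-cycle percentage `i`,
sweep the channel value at `i` over `n_levels = 11` uniform levels from 0
to the maximum observed value (per-percentage maximum by default, global
maximum optionally), re-predict every trial closed-loop, and record the
RMSE between predictions and measured costs. `rmse_mean[i]` and
`rmse_sd[i]` are the mean and sd over the 11 levels — one value and one
bar per percentage, matching how such curves are plotted. Perturbations
are applied in physical units before re-standardization; input trials are
never mutated (enforced by test). Channels are perturbed one at a time.
11 levels give 10 % resolution of the perturbation range. With the
per-percentage rule, percentages where the channel is constant across
trials (e.g. swing for the vertical GRF) have zero perturbation range and
reproduce the baseline RMSE exactly — a built-in self-check.

`find_critical_phases` returns the indices of the largest strict local
maxima of `rmse_mean` (endpoints compared one-sided), descending, ties
toward the lower index; a constant curve has no peaks.

## Evaluation suite

Per partition (train/validation/test/all): MSE in (W/kg)², Pearson R with
the exact two-sided t-transform p-value (`t = r√((n−2)/(1−r²))`, n−2 df);
correlation is omitted with a recorded warning for partitions under 3
trials. Over all trials: a 20-bin error histogram of `target − pred`
(uniform bins spanning the error range, counts conserved), accuracy as
the percentage of trials with `|pred − target| ≤ 0.20·|target|`, and
classification metrics from a **median split**: trials above the median
measured cost form the positive class, predictions are binarized about
the same threshold, and recall/precision are reported in percent, F1 as a
fraction. The median split is a documented convention — regression-derived
class metrics need *some* class definition, and the median is the least
arbitrary — not an attempt to reproduce any particular published rule.

## Numerical choices and degenerate inputs

* Standardization guards: features/targets with sd < 1e-12 fall back to
  sd 1 (prevents division blow-ups on constant channels).
* LM solves use `numpy.linalg.solve` on the damped normal equations;
  `μ > 0` guarantees non-singularity.
* Zero-variance inputs to correlation, single-class targets for the
  median split, zero targets for tolerance accuracy, and empty
  stride/trial collections all raise typed errors rather than returning
  NaN.
* Degenerate error spread in the histogram (all errors equal) collapses
  to a single occupied bin.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit config fields; derived seeds use fixed documented offsets.

## Problem sizes used by the tests and acceptance script

The test suite and `scripts/acceptance.py` run the full algorithms at
reduced scale, chosen as the smallest sizes at which each property is
cleanly expressed: cohorts of 24–270 trials, training capped at 5–400
epochs (recovery runs use 400; smoke runs 5–60), grid sweeps of 2–3
hidden sizes × 1–2 delays × 1–2 repetitions instead of 49 × 4 × 1000, and
3 reiterations where a representative model is needed. The full-scale
sweep is available unchanged through `gaitmet optimize` flags.

## Known limitations

* The trial-level split leaks participant identity between partitions
  (see above); subject-wise generalization is not what the held-out
  metrics measure.
* The scalar-target bridge (replication + closed-loop averaging) is one
  of several defensible readings of how a per-trial target meets a
  time-series network; per-step cost profiles produced by the model are a
  modeling artifact, not measured within-stride cost.
* The PDP perturbations push inputs off the data manifold; RMSE responses
  at percentages far from any observed variation reflect extrapolation
  behavior of the network, which is why peak-location claims are only
  made on designs where the informative variation is localized.
* Single hidden layer only; no Bayesian regularization; no GPU path.
  These were not needed at the problem sizes the pipeline targets.
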