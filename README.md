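# gaitmet

Predicting the **net metabolic cost of walking** from gait-cycle waveforms
with NARX recurrent neural networks.

## The problem

Measuring how much energy a person spends while walking normally requires
indirect calorimetry, which needs minutes of steady-state breathing per
condition — impractical for patients with limited walking endurance and
useless for resolving cost *within* a stride. Biomechanical signals that
are cheap to record on every stride — ground-reaction forces (GRF) and
sagittal joint moments — carry much of the same information. `gaitmet`
implements a pipeline that learns the mapping

```
{GRF_ver(t), GRF_ap(t)}            ─┐
                                    ├─►  NARX network  ─►  net metabolic rate (W/kg)
{Hip_M(t), Knee_M(t), Ankle_M(t)}  ─┘
```

from stride-averaged, mass-normalized waveforms sampled at 100 gait-cycle
percentages (GRF in N/kg, moments in N·m/kg), one scalar calorimetry
target per trial. Two model families are supported, one driven by the two
GRF components and one by the three joint moments.

The network is a nonlinear autoregressive model with exogenous inputs
(NARX): at gait-cycle step *t* it sees the current and *d* delayed values
of each input channel plus *q* delayed target values, one tanh hidden
layer, linear output:

```
ŷ(t) = W_out · tanh( W_in · [x(t), …, x(t−d), y(t−1), …, y(t−q)] + b ) + b_out
```

Training is open-loop (series–parallel: true delayed targets in the
feedback taps) with full-batch **Levenberg–Marquardt** and
validation-based early stopping; trial-level prediction closes the loop
and averages the per-step outputs. The package also provides:

* a **synthetic cohort generator** emulating a two-study repeated-measures
  design (10 participants × 15 footwear conditions + 10 participants × 12
  exoskeleton conditions = 270 trials at 1.25 m/s) with a documented
  linear generative law linking four waveform features to metabolic cost —
  so every pipeline stage is testable against known ground truth;
* preprocessing (resampling to the 100-point cycle grid, mass
  normalization, stride averaging, the 70/15/15 split);
* an exhaustive **architecture search** over hidden-layer size (2–50),
  delays (1–4) and repeated re-initializations, plus 5-fold
  cross-validation;
* the full **evaluation suite**: per-partition MSE, Pearson R with
  p-values, error histograms, accuracy within a ±20 % error margin, and
  median-split recall/precision/F1;
* **gait-phase sensitivity analysis** (perturbation partial-dependence):
  sweep one gait-cycle percentage of one channel over levels from zero to
  its maximum observed value and record the resulting prediction RMSE,
  locating the phases — push-off in particular — the model leans on.

## Worked example

```python
import gaitmet as gm

trials = gm.generate_cohort(gm.CohortDesign(seed=1))          # 270 synthetic trials
split  = gm.split_dataset([t.trial_id for t in trials], seed=1)

cfg   = gm.NarxConfig(hidden_size=6, input_delays=2, max_epochs=200, seed=1)
model = gm.fit_gait_model(trials, split.train_ids, split.validation_ids,
                          gm.GRF_CHANNELS, cfg)

report = gm.evaluate_model(model, split, trials)
for part in ("train", "validation", "test"):
    e = report.partitions[part]
    print(f"{part:<10s} n={e['n']:<3d} MSE={e['mse']:.4f} (W/kg)^2  "
          f"R={e['r']:.3f}  p={e['p_value']:.2e}")
print(f"accuracy within +-20%: {report.accuracy_pct:.1f}%  F1={report.f1:.2f}")
```

prints

```
train      n=188 MSE=0.0394 (W/kg)^2  R=0.940  p=1.05e-88
validation n=41  MSE=0.0415 (W/kg)^2  R=0.956  p=2.09e-22
test       n=41  MSE=0.0477 (W/kg)^2  R=0.967  p=1.12e-24
accuracy within +-20%: 100.0%  F1=0.86
```

The cohort's metabolic costs span ≈3.1–5.0 W/kg (plausible for walking at
1.25 m/s); the held-out R of 0.967 says the 6-hidden/2-delay GRF network
recovers the generative waveform→cost mapping from the two force channels
alone, and every test trial lands within the ±20 % clinical error margin.

The same pipeline is available from the shell:

```bash
gaitmet generate --seed 1 --out cohort.csv
gaitmet split    --cohort cohort.csv --seed 1 --out split.csv
gaitmet train    --cohort cohort.csv --split split.csv --model grf \
                 --hidden 6 --delays 2 --out model.json
gaitmet evaluate --cohort cohort.csv --split split.csv --model model.json \
                 --out evaluation.json
gaitmet pdp      --cohort cohort.csv --model model.json --out pdp.csv
gaitmet report   --evaluation evaluation.json --pdp pdp.csv --out summary.json
```

Every command drops a JSON snapshot of its resolved options next to its
output, so any run can be replayed exactly.

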