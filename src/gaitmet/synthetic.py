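"""Synthetic walking cohorts with a known waveform -> metabolic-cost law.

The experimental datasets this pipeline targets (treadmill walking at
1.25 m/s, stride-averaged ground-reaction forces and sagittal joint
moments, net metabolic rate from indirect calorimetry) are not publicly
deposited, so every downstream stage is exercised on cohorts produced
here.  The generator emulates the published study layout -- two
sub-studies, one on footwear (10 participants x 15 conditions) and one
on a hip exoskeleton (10 participants x 12 conditions), 270 trials in
total -- and ties each trial's scalar metabolic cost to its waveforms
through a fixed, fully documented linear law, so that recovery of the
mapping by a trained network is provable rather than merely plausible.

Waveform templates
------------------
All waveforms live on the 100-point gait-cycle grid ``t_i = i/99`` for
``i = 0..99`` (heel-strike at 0 %, next ipsilateral heel-strike at
100 %).  Stance occupies ``t < stance_fraction``; swing is the
remainder, where both GRF components are identically zero.

The basic building block is the raised cosine bump

    rc(x; c, w) = 0.5 * (1 + cos(2*pi*(x - c)/w))   if |x - c| <= w/2
                  0                                  otherwise

which is C1-smooth, non-negative, and compactly supported.

* Vertical GRF: two raised-cosine bumps in normalized stance time
  ``s = t / stance_fraction``::

      grf_ver(s) = a1 * rc(s; 0.30 + j1, 0.62) + a2 * rc(s; 0.72 + j2, 0.62)

  reproducing the canonical double-hump (loading-response and push-off
  peaks with a mid-stance valley).

* Anterior-posterior GRF: one sine period over stance,
  ``grf_ap(s) = -a3 * sin(2*pi*(s - j3))``, braking (negative) in early
  stance and propulsive (positive) in late stance; the stance samples
  are then mean-centred so the discrete net AP impulse over the cycle
  is exactly zero (steady treadmill speed).

* Joint moments: sums of <= 4 signed raised-cosine components on the
  full cycle; see :data:`MOMENT_COMPONENTS` for the per-joint centres
  and widths.  The default ankle template peaks at 48 % of the cycle
  (push-off plantarflexion).

Generative metabolic-cost law
-----------------------------
For trial waveforms the feature vector is

    f1 = positive AP impulse      = mean_i max(grf_ap_i, 0)
    f2 = mean absolute ankle moment = mean_i |ankle_m_i|
    f3 = mean(|hip_m_i| + |knee_m_i|)
    f4 = peak vertical GRF        = max_i grf_ver_i

and the cost is ``met_cost = c0 + w . f + noise`` with Gaussian noise.
Participant- and condition-level heterogeneity enters as log-normal
multiplicative amplitude effects per channel (drawn once per
participant and once per condition, reused across that unit's trials),
which preserves the swing-phase-zero and non-negativity invariants of
the vertical GRF for every trial at every seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import InvalidDesignError, NoDataError

N_POINTS = 100
#: Gait-cycle grid in fractions of the cycle, 0 .. 1 inclusive.
CYCLE_GRID = np.arange(N_POINTS) / (N_POINTS - 1)

CHANNELS = ("grf_ver", "grf_ap", "hip_m", "knee_m", "ankle_m")
JOINTS = ("hip", "knee", "ankle")

#: Per-joint raised-cosine components as (relative amplitude, centre, width)
#: in cycle fractions.  Relative amplitudes are scaled by the per-channel
#: amplitude mean of the design; signs encode extensor/flexor direction.
MOMENT_COMPONENTS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "hip": ((1.0, 0.12, 0.50), (-0.8, 0.55, 0.55)),
    "knee": ((0.9, 0.15, 0.30), (-0.5, 0.45, 0.40), (0.3, 0.75, 0.30)),
    # ankle: sharp plantarflexion peak at push-off (~45 %), a gentler
    # mid-stance rise, and a small early dorsiflexion dip
    "ankle": ((1.0, 0.45, 0.38), (0.35, 0.22, 0.28), (-0.25, 0.05, 0.12)),
}

#: Relative sizes of (first peak, second peak) of the vertical GRF and of
#: the AP sine amplitude; scaled by the design's grf_ver / grf_ap means.
GRF_VER_RELATIVE = (1.0, 0.95)

#: Weights of the generative cost law over (f1, f2, f3, f4); see module
#: docstring for the feature definitions.  Units: W/kg per feature unit.
DEFAULT_COST_WEIGHTS = (2.0, 2.5, 1.0, 0.08)


@dataclass
class GaitTrial:
    """One walking trial: five gait-cycle waveforms plus the scalar target.

    Waveforms are mass-normalized (GRF in N/kg, moments in N*m/kg) and
    sampled at 100 gait-cycle percentages; ``met_cost`` is the net
    metabolic rate in W/kg.
    """

    trial_id: str
    study: str
    participant_id: str
    condition_id: str
    grf_ver: np.ndarray
    grf_ap: np.ndarray
    hip_m: np.ndarray
    knee_m: np.ndarray
    ankle_m: np.ndarray
    met_cost: float

    def waveform(self, channel: str) -> np.ndarray:
        if channel not in CHANNELS:
            raise KeyError(f"unknown channel {channel!r}")
        return getattr(self, channel)

    def __post_init__(self) -> None:
        for ch in CHANNELS:
            arr = np.asarray(getattr(self, ch), dtype=float)
            if arr.shape != (N_POINTS,):
                raise ValueError(f"{ch} must have exactly {N_POINTS} samples")
            setattr(self, ch, arr)


@dataclass
class CohortDesign:
    """Parameters of the synthetic two-study cohort and its cost law.

    Defaults mirror the published study layout: a footwear study
    (10 participants x 15 conditions) and a hip-exoskeleton study
    (10 participants x 12 conditions), 270 trials in total, stance
    occupying the first 60 % of the cycle.
    """

    studies: tuple[tuple[str, int, int], ...] = (
        ("footwear", 10, 15),
        ("exoskeleton", 10, 12),
    )
    stance_fraction: float = 0.60
    waveform_amplitude_means: dict[str, float] = field(
        default_factory=lambda: {
            "grf_ver": 10.5,  # N/kg, ~1.07 body weight at the peaks
            "grf_ap": 1.8,  # N/kg, ~0.18 body weight braking/propulsion
            "hip_m": 1.0,  # N*m/kg
            "knee_m": 0.7,  # N*m/kg
            "ankle_m": 1.5,  # N*m/kg plantarflexion peak
        }
    )
    #: Log-scale sd of the per-participant amplitude multiplier, per channel.
    participant_effect_sd: dict[str, float] = field(
        default_factory=lambda: {ch: 0.08 for ch in CHANNELS}
    )
    condition_effect_sd: dict[str, float] = field(
        default_factory=lambda: {ch: 0.10 for ch in CHANNELS}
    )
    measurement_noise_sd: dict[str, float] = field(
        default_factory=lambda: {ch: 0.03 for ch in CHANNELS}
    )
    cost_baseline: float = 1.0  # W/kg
    cost_weights: tuple[float, float, float, float] = DEFAULT_COST_WEIGHTS
    cost_noise_sd: float = 0.10  # W/kg, calorimetry repeatability stand-in
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return sum(n_p * n_c for _, n_p, n_c in self.studies)

    def validate(self) -> None:
        if not 0.4 <= self.stance_fraction <= 0.8:
            raise InvalidDesignError(
                f"stance_fraction must lie in [0.4, 0.8], got {self.stance_fraction}"
            )
        for name, table in (
            ("participant_effect_sd", self.participant_effect_sd),
            ("condition_effect_sd", self.condition_effect_sd),
            ("measurement_noise_sd", self.measurement_noise_sd),
        ):
            for ch, sd in table.items():
                if sd < 0:
                    raise InvalidDesignError(f"{name}[{ch}] must be >= 0, got {sd}")
        if self.cost_noise_sd < 0:
            raise InvalidDesignError("cost_noise_sd must be >= 0")
        for ch, amp in self.waveform_amplitude_means.items():
            if amp <= 0:
                raise InvalidDesignError(f"amplitude mean for {ch} must be > 0")
        if not self.studies:
            raise InvalidDesignError("design must contain at least one study")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["studies"] = [list(s) for s in self.studies]
        d["cost_weights"] = list(self.cost_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortDesign":
        d = dict(d)
        if "studies" in d:
            d["studies"] = tuple(tuple(s) for s in d["studies"])
        if "cost_weights" in d:
            d["cost_weights"] = tuple(d["cost_weights"])
        return cls(**d)


def _raised_cosine(x: np.ndarray, centre: float, width: float) -> np.ndarray:
    u = (x - centre) / width
    out = np.where(np.abs(u) <= 0.5, 0.5 * (1.0 + np.cos(2.0 * np.pi * u)), 0.0)
    return out


def grf_template(
    stance_fraction: float,
    amplitudes: Sequence[float] = (10.5, 9.975, 1.8),
    phase_jitter: Sequence[float] = (0.0, 0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Vertical and anterior-posterior GRF templates on the 100-point grid.

    Parameters
    ----------
    stance_fraction:
        Fraction of the cycle in stance, in [0.4, 0.8].
    amplitudes:
        ``(a1, a2, a3)`` -- first and second vertical peaks and the AP
        sine amplitude, in N/kg; all must be positive.
    phase_jitter:
        ``(j1, j2, j3)`` additive shifts of the bump centres / sine
        phase, in normalized stance time.

    Returns
    -------
    (grf_ver, grf_ap):
        Both zero over swing; ``grf_ver >= 0`` everywhere; the discrete
        mean of ``grf_ap`` over the cycle is exactly zero (stance
        samples are mean-centred), so the net AP impulse vanishes.
    """
    if not 0.4 <= stance_fraction <= 0.8:
        raise InvalidDesignError(
            f"stance_fraction must lie in [0.4, 0.8], got {stance_fraction}"
        )
    a1, a2, a3 = amplitudes
    if a1 <= 0 or a2 <= 0 or a3 <= 0:
        raise InvalidDesignError("GRF amplitudes must be > 0")
    j1, j2, j3 = phase_jitter

    stance = CYCLE_GRID < stance_fraction
    s = np.where(stance, CYCLE_GRID / stance_fraction, 0.0)

    ver = a1 * _raised_cosine(s, 0.30 + j1, 0.62) + a2 * _raised_cosine(
        s, 0.72 + j2, 0.62
    )
    ver = np.where(stance, ver, 0.0)

    ap = -a3 * np.sin(2.0 * np.pi * (s - j3))
    ap = np.where(stance, ap, 0.0)
    # Steady-speed contract: zero net AP impulse over the cycle.
    n_stance = int(stance.sum())
    ap = np.where(stance, ap - ap[stance].sum() / n_stance, 0.0)
    return ver, ap


def moment_template(
    joint: str,
    amplitudes: Sequence[float] | None = None,
    phase_jitter: Sequence[float] | None = None,
    scale: float = 1.0,
) -> np.ndarray:
    """Sagittal joint-moment template: a sum of signed raised cosines.

    The waveform is ``sum_k A_k * rc(t; c_k + j_k, w_k)`` on the cycle
    grid, with per-joint components from :data:`MOMENT_COMPONENTS`.
    ``amplitudes`` overrides the component amplitudes ``A_k`` (already
    including sign); when omitted they default to the relative
    amplitudes times ``scale``.  At default phases the ankle template's
    absolute maximum falls in the 40-60 % push-off window.
    """
    if joint not in MOMENT_COMPONENTS:
        raise InvalidDesignError(f"unknown joint {joint!r}; expected one of {JOINTS}")
    comps = MOMENT_COMPONENTS[joint]
    if amplitudes is None:
        amplitudes = [rel * scale for rel, _, _ in comps]
    if len(amplitudes) != len(comps):
        raise InvalidDesignError(
            f"{joint} template has {len(comps)} components, got "
            f"{len(amplitudes)} amplitudes"
        )
    if phase_jitter is None:
        phase_jitter = [0.0] * len(comps)
    if not np.all(np.isfinite(amplitudes)):
        raise InvalidDesignError("moment amplitudes must be finite")

    wave = np.zeros(N_POINTS)
    for a_k, (_, c_k, w_k), j_k in zip(amplitudes, comps, phase_jitter):
        wave += a_k * _raised_cosine(CYCLE_GRID, c_k + j_k, w_k)
    return wave


class CostFeatures(NamedTuple):
    """The four waveform features entering the generative cost law."""

    ap_impulse_pos: float
    ankle_abs_mean: float
    hip_knee_abs_mean: float
    grf_ver_peak: float


def cost_features(
    grf_ver: np.ndarray,
    grf_ap: np.ndarray,
    hip_m: np.ndarray,
    knee_m: np.ndarray,
    ankle_m: np.ndarray,
) -> CostFeatures:
    """Feature vector ``f`` of the generative law (see module docstring)."""
    return CostFeatures(
        ap_impulse_pos=float(np.mean(np.maximum(grf_ap, 0.0))),
        ankle_abs_mean=float(np.mean(np.abs(ankle_m))),
        hip_knee_abs_mean=float(np.mean(np.abs(hip_m) + np.abs(knee_m))),
        grf_ver_peak=float(np.max(grf_ver)),
    )


def metabolic_ground_truth(
    trial_waveforms: dict[str, np.ndarray],
    design: CohortDesign,
    noise_draw: float = 0.0,
) -> float:
    """Metabolic cost of a trial under the generative law, in W/kg.

    ``met_cost = c0 + w . f(waveforms) + noise_draw``; the noise draw is
    supplied by the caller so the law itself stays deterministic.
    """
    f = cost_features(**{ch: np.asarray(trial_waveforms[ch]) for ch in CHANNELS})
    w = np.asarray(design.cost_weights, dtype=float)
    return float(design.cost_baseline + w @ np.asarray(f) + noise_draw)


def generate_cohort(design: CohortDesign | None = None) -> list[GaitTrial]:
    """Generate the full synthetic cohort for a design.

    Returns exactly ``sum(n_participants * n_conditions)`` trials.
    Participant and condition amplitude effects are drawn once per unit
    and reused across that unit's trials; identical seeds give bitwise
    identical cohorts.
    """
    if design is None:
        design = CohortDesign()
    design.validate()
    rng = np.random.default_rng(design.seed)
    amp_means = design.waveform_amplitude_means
    trials: list[GaitTrial] = []

    for study, n_part, n_cond in design.studies:
        # One latent gait-intensity factor per participant and one per
        # condition; channels respond to it with their own sensitivities
        # (the per-channel effect sds).  This couples the channels the way
        # repeated-measures gait data are coupled: a more vigorous
        # participant or a harder condition scales forces and moments
        # together.  Measurement noise stays independent per channel.
        z_part = rng.normal(0.0, 1.0, size=n_part)
        z_cond = rng.normal(0.0, 1.0, size=n_cond)
        for p in range(n_part):
            for c in range(n_cond):
                m_eff = {
                    ch: rng.normal(0.0, design.measurement_noise_sd[ch])
                    for ch in CHANNELS
                }
                scale = {
                    ch: amp_means[ch]
                    * np.exp(
                        design.participant_effect_sd[ch] * z_part[p]
                        + design.condition_effect_sd[ch] * z_cond[c]
                        + m_eff[ch]
                    )
                    for ch in CHANNELS
                }
                ver, ap = grf_template(
                    design.stance_fraction,
                    amplitudes=(
                        scale["grf_ver"] * GRF_VER_RELATIVE[0],
                        scale["grf_ver"] * GRF_VER_RELATIVE[1],
                        scale["grf_ap"],
                    ),
                )
                waves = {
                    "grf_ver": ver,
                    "grf_ap": ap,
                    "hip_m": moment_template("hip", scale=scale["hip_m"]),
                    "knee_m": moment_template("knee", scale=scale["knee_m"]),
                    "ankle_m": moment_template("ankle", scale=scale["ankle_m"]),
                }
                noise = (
                    rng.normal(0.0, design.cost_noise_sd)
                    if design.cost_noise_sd > 0
                    else 0.0
                )
                met = metabolic_ground_truth(waves, design, noise_draw=noise)
                trials.append(
                    GaitTrial(
                        trial_id=f"{study}_p{p + 1:02d}_c{c + 1:02d}",
                        study=study,
                        participant_id=f"{study}_p{p + 1:02d}",
                        condition_id=f"c{c + 1:02d}",
                        met_cost=met,
                        **waves,
                    )
                )
    return trials


def pushoff_ankle_cohort(
    n_trials: int = 150,
    amplitude_sd: float = 0.15,
    seed: int = 0,
) -> list[GaitTrial]:
    """A cohort whose metabolic cost loads only on ankle push-off.

    Every waveform except the ankle moment is fixed at its template
    default; the ankle channel contains only the push-off
    plantarflexion bump, whose amplitude varies log-normally across
    trials, and the cost law weights only the ankle feature.  Because
    the sole across-trial signal lives in the push-off window
    (~40-60 % of the cycle), a correctly working perturbation
    sensitivity analysis must locate its RMSE peak there -- which makes
    this cohort the sharp probe for phase-attribution checks.
    """
    if n_trials < 1:
        raise NoDataError("need at least one trial")
    rng = np.random.default_rng(seed)
    design = CohortDesign(cost_weights=(0.0, 2.5, 0.0, 0.0), cost_noise_sd=0.0)
    ver, ap = grf_template(design.stance_fraction)
    hip = moment_template("hip", scale=design.waveform_amplitude_means["hip_m"])
    knee = moment_template("knee", scale=design.waveform_amplitude_means["knee_m"])
    base_amp = design.waveform_amplitude_means["ankle_m"]
    trials = []
    for i in range(n_trials):
        a = base_amp * np.exp(rng.normal(0.0, amplitude_sd))
        ankle = moment_template("ankle", amplitudes=[a, 0.0, 0.0])
        waves = {
            "grf_ver": ver,
            "grf_ap": ap,
            "hip_m": hip,
            "knee_m": knee,
            "ankle_m": ankle,
        }
        trials.append(
            GaitTrial(
                trial_id=f"pushoff_{i:03d}",
                study="pushoff",
                participant_id=f"p{i:03d}",
                condition_id="c01",
                met_cost=metabolic_ground_truth(waves, design),
                **{k: v.copy() for k, v in waves.items()},
            )
        )
    return trials


class SeriesSample(NamedTuple):
    """A generic NARX training sample: exogenous channels plus a target series.

    ``inputs`` has shape (n_channels, 100); ``target`` has shape (100,).
    Gait trials map onto this by replicating the scalar metabolic cost
    across all 100 steps (see :func:`gaitmet.narx.trials_to_series`).
    """

    inputs: np.ndarray
    target: np.ndarray


def lagged_series_samples(
    n_samples: int,
    lag: int = 2,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> list[SeriesSample]:
    """Single-channel series whose target has an effective memory of ``lag``.

    ``y(t) = 0.5 x(t) + 1.2 x(t - lag) + noise`` with ``x`` a smoothed
    Gaussian random walk; a NARX model needs at least ``lag`` input
    delays to represent the map, which makes these samples a sharp
    probe of delay selection in the architecture search.
    """
    if n_samples < 1:
        raise NoDataError("need at least one sample")
    rng = np.random.default_rng(seed)
    samples = []
    kernel = np.ones(5) / 5.0
    for _ in range(n_samples):
        x_ext = np.convolve(rng.normal(size=N_POINTS + lag + 4), kernel, mode="same")
        x_ext = x_ext[: N_POINTS + lag]
        x = x_ext[lag:]
        y = 0.5 * x + 1.2 * x_ext[:N_POINTS]
        y = y + rng.normal(0.0, noise_sd, size=N_POINTS)
        samples.append(SeriesSample(inputs=x[None, :].copy(), target=y))
    return samples
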