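"""Standardization of raw gait time series onto the 100-point cycle grid.

Raw force-plate and inverse-dynamics series arrive at heterogeneous
sample rates; everything downstream works on mass-normalized,
stride-averaged waveforms resampled to 100 points spanning 0-100 % of
the gait cycle (both heel-strikes included, grid ``(i-1)/99``).  The
module also owns the 70/15/15 trial-level split used for network
training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    InvalidDataError,
    InvalidMassError,
    NoDataError,
    ShapeError,
    TooFewTrialsError,
    TooShortSeriesError,
)

N_POINTS = 100


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partition of trial ids.

    Sizes follow the ceiling rule: ``|val| = ceil(r_val * N)``,
    ``|test| = ceil(r_test * N)``, train takes the remainder — the only
    rounding that yields 188/41/41 for 270 trials at 70/15/15.
    """

    train_ids: list[str]
    validation_ids: list[str]
    test_ids: list[str]
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    stratify_by: str | None = None

    def __post_init__(self) -> None:
        parts = [set(self.train_ids), set(self.validation_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise ShapeError("split partitions overlap")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train_ids), len(self.validation_ids), len(self.test_ids))

    def partition_of(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for name, ids in (
            ("train", self.train_ids),
            ("validation", self.validation_ids),
            ("test", self.test_ids),
        ):
            for tid in ids:
                out[tid] = name
        return out


def resample_to_gait_cycle(series: Sequence[float]) -> np.ndarray:
    """Linearly interpolate a series onto 100 uniform gait-cycle points.

    Query points are ``t_i = (i-1)/99`` of the cycle for ``i = 1..100``;
    the first and last input samples are preserved exactly, and a
    length-100 input is returned unchanged (identity on the target
    grid).
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise ShapeError(f"expected 1-D series, got shape {arr.shape}")
    if arr.size < 2:
        raise TooShortSeriesError(f"series needs >= 2 samples, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise InvalidDataError("series contains non-finite values")
    if arr.size == N_POINTS:
        return arr.copy()
    src = np.linspace(0.0, 1.0, arr.size)
    dst = np.linspace(0.0, 1.0, N_POINTS)
    return np.interp(dst, src, arr)


def normalize_by_mass(series: Sequence[float], mass: float) -> np.ndarray:
    """Divide a force (N) or moment (N*m) series by body mass in kg."""
    if mass <= 0 or not math.isfinite(mass):
        raise InvalidMassError(f"mass must be > 0 kg, got {mass}")
    return np.asarray(series, dtype=float) / mass


def stride_average(strides: Sequence[Sequence[float]]) -> np.ndarray:
    """Pointwise mean waveform across strides (each on the 100-point grid)."""
    if len(strides) == 0:
        raise NoDataError("no strides to average")
    mat = [np.asarray(s, dtype=float) for s in strides]
    if any(s.shape != (N_POINTS,) for s in mat):
        raise ShapeError(f"all strides must have exactly {N_POINTS} samples")
    return np.mean(mat, axis=0)


def split_dataset(
    trial_ids: Sequence[str],
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    stratify_labels: Sequence[str] | None = None,
) -> DatasetSplit:
    """Randomly partition trials into train/validation/test.

    A seeded uniform shuffle is followed by the ceiling rule:
    ``ceil(r_val*N)`` ids to validation, ``ceil(r_test*N)`` to test,
    the remainder to train.  For N=270 at 70/15/15 this reproduces the
    188/41/41 partition.  When ``stratify_labels`` is given (one label
    per trial, e.g. the study name), the rule is applied within each
    label group and the groups concatenated.
    """
    ids = list(trial_ids)
    n = len(ids)
    if n < 3:
        raise TooFewTrialsError(f"need at least 3 trials to split, got {n}")
    if len(ids) != len(set(ids)):
        raise InvalidDataError("trial ids must be unique")
    if not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise InvalidDataError(f"ratios must sum to 1, got {ratios}")

    rng = np.random.default_rng(seed)

    def _assign(group: list[str]) -> tuple[list[str], list[str], list[str]]:
        order = list(np.array(group, dtype=object)[rng.permutation(len(group))])
        n_g = len(order)
        n_val = math.ceil(ratios[1] * n_g)
        n_test = math.ceil(ratios[2] * n_g)
        if n_val + n_test >= n_g:
            raise TooFewTrialsError(
                f"group of {n_g} trials leaves no training data under {ratios}"
            )
        return (
            order[n_val + n_test :],
            order[:n_val],
            order[n_val : n_val + n_test],
        )

    if stratify_labels is None:
        train, val, test = _assign(ids)
        strat = None
    else:
        if len(stratify_labels) != n:
            raise ShapeError("stratify_labels must match trial_ids in length")
        train, val, test = [], [], []
        groups: dict[str, list[str]] = {}
        for tid, lab in zip(ids, stratify_labels):
            groups.setdefault(lab, []).append(tid)
        for lab in sorted(groups):
            tr, va, te = _assign(groups[lab])
            train += tr
            val += va
            test += te
        strat = "label"

    return DatasetSplit(
        train_ids=train,
        validation_ids=val,
        test_ids=test,
        ratios=tuple(ratios),
        seed=seed,
        stratify_by=strat,
    )
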