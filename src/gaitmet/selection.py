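"""Architecture search and cross-validation for NARX cost models.

The search is a plain exhaustive enumeration over hidden-layer size,
delay count, and repeated random re-initializations (the published
sweep spans hidden sizes 2-50, delays 1-4 and 1000 reiterations per
cell; the ranges and repetition count are arguments here so the same
loop runs at desk scale).  The winning cell is the exact argmin of
validation MSE, with ties broken toward the smaller network: fewer
hidden units first, then fewer delays, then the lower repetition
index.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import InvalidConfigError, TooFewTrialsError
from .evaluation import mse, pearson_r
from .narx import (
    NarxConfig,
    fit_gait_model,
    forward,
    predict_trials,
    train,
    _pooled_regressors,
)
from .preprocess import DatasetSplit, split_dataset
from .synthetic import GaitTrial, SeriesSample

FULL_SWEEP_HIDDEN_RANGE = (2, 50)
FULL_SWEEP_DELAY_RANGE = (1, 4)
FULL_SWEEP_N_REPETITIONS = 1000


@dataclass(frozen=True)
class SearchRecord:
    """Outcome of one grid cell: configuration plus partition metrics."""

    hidden_size: int
    delays: int
    repetition: int
    repetition_seed: int
    mse_train: float
    mse_val: float
    mse_test: float
    r_train: float
    r_val: float
    r_test: float

    @property
    def sort_key(self) -> tuple:
        return (self.mse_val, self.hidden_size, self.delays, self.repetition)


def _partition_metrics(preds: np.ndarray, targets: np.ndarray) -> tuple[float, float]:
    m = mse(preds, targets)
    if preds.size >= 3 and np.ptp(targets) > 0 and np.ptp(preds) > 0:
        r, _ = pearson_r(preds, targets)
    else:
        r = math.nan
    return m, r


def grid_search(
    trials: Sequence[GaitTrial],
    split: DatasetSplit,
    channels: Sequence[str],
    hidden_values: Sequence[int],
    delay_values: Sequence[int],
    n_repetitions: int = 1,
    base_seed: int = 0,
    config: NarxConfig | None = None,
    progress: Callable[[SearchRecord], None] | None = None,
) -> tuple[SearchRecord, list[SearchRecord]]:
    """Exhaustive (hidden, delay, repetition) search on a gait cohort.

    Trains one model per cell with repetition seeds ``base_seed + rep``
    and records trial-level closed-loop MSE and Pearson R on each
    partition.  Returns the argmin-of-validation-MSE record plus the
    full audit list.
    """
    if not len(hidden_values) or not len(delay_values) or n_repetitions < 1:
        raise InvalidConfigError("hidden/delay ranges and repetitions must be non-empty")
    base = config or NarxConfig()
    by_id = {t.trial_id: t for t in trials}
    parts = {
        "train": [by_id[i] for i in split.train_ids],
        "val": [by_id[i] for i in split.validation_ids],
        "test": [by_id[i] for i in split.test_ids],
    }
    targets = {k: np.array([t.met_cost for t in v]) for k, v in parts.items()}

    records: list[SearchRecord] = []
    for hidden in hidden_values:
        for delay in delay_values:
            for rep in range(n_repetitions):
                seed = base_seed + rep
                cfg = dataclasses.replace(
                    base,
                    hidden_size=int(hidden),
                    input_delays=int(delay),
                    feedback_delays=None,
                    seed=seed,
                )
                model = fit_gait_model(
                    trials, split.train_ids, split.validation_ids, channels, cfg
                )
                metrics = {}
                for k in ("train", "val", "test"):
                    preds = predict_trials(model, parts[k])
                    metrics[k] = _partition_metrics(preds, targets[k])
                rec = SearchRecord(
                    hidden_size=int(hidden),
                    delays=int(delay),
                    repetition=rep,
                    repetition_seed=seed,
                    mse_train=metrics["train"][0],
                    mse_val=metrics["val"][0],
                    mse_test=metrics["test"][0],
                    r_train=metrics["train"][1],
                    r_val=metrics["val"][1],
                    r_test=metrics["test"][1],
                )
                records.append(rec)
                if progress is not None:
                    progress(rec)
    best = min(records, key=lambda r: r.sort_key)
    return best, records


def grid_search_series(
    train_samples: Sequence[SeriesSample],
    val_samples: Sequence[SeriesSample],
    hidden_values: Sequence[int],
    delay_values: Sequence[int],
    n_repetitions: int = 1,
    base_seed: int = 0,
    config: NarxConfig | None = None,
) -> tuple[SearchRecord, list[SearchRecord]]:
    """Grid search on raw series samples with per-step open-loop MSE.

    Used when the target genuinely varies within a series (e.g. probes
    of the delay structure); metrics are computed on the pooled
    open-loop regressor matrices rather than per-trial scalars.
    """
    if not len(hidden_values) or not len(delay_values) or n_repetitions < 1:
        raise InvalidConfigError("hidden/delay ranges and repetitions must be non-empty")
    base = config or NarxConfig()
    records: list[SearchRecord] = []
    for hidden in hidden_values:
        for delay in delay_values:
            for rep in range(n_repetitions):
                seed = base_seed + rep
                cfg = dataclasses.replace(
                    base,
                    hidden_size=int(hidden),
                    input_delays=int(delay),
                    feedback_delays=None,
                    n_input_channels=np.atleast_2d(train_samples[0].inputs).shape[0],
                    seed=seed,
                )
                model = train(cfg, train_samples, val_samples)
                out = {}
                for k, samples in (("train", train_samples), ("val", val_samples)):
                    X, y = _pooled_regressors(model, samples)
                    preds = forward(model, X)
                    out[k] = _partition_metrics(
                        model.y_mean + model.y_std * preds,
                        model.y_mean + model.y_std * y,
                    )
                records.append(
                    SearchRecord(
                        hidden_size=int(hidden),
                        delays=int(delay),
                        repetition=rep,
                        repetition_seed=seed,
                        mse_train=out["train"][0],
                        mse_val=out["val"][0],
                        mse_test=math.nan,
                        r_train=out["train"][1],
                        r_val=out["val"][1],
                        r_test=math.nan,
                    )
                )
    best = min(records, key=lambda r: r.sort_key)
    return best, records


def kfold_cv(
    config: NarxConfig,
    trials: Sequence[GaitTrial],
    channels: Sequence[str],
    k: int = 5,
    seed: int = 0,
) -> dict:
    """k-fold cross-validation of one configuration at the trial level.

    A seeded shuffle assigns trials to k near-equal folds; each fold is
    held out in turn while the remainder is split 85/15 into training
    and an early-stopping validation carve-out.  Held-out trials are
    scored with closed-loop predictions.  Returns mean +- sd of the
    fold MSE and Pearson R.
    """
    n = len(trials)
    if k < 2:
        raise InvalidConfigError("k must be >= 2")
    if n < k:
        raise TooFewTrialsError(f"{n} trials cannot form {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    fold_mse, fold_r = [], []
    for fold in folds:
        test_idx = set(int(i) for i in fold)
        rest = [trials[int(i)] for i in order if int(i) not in test_idx]
        held = [trials[int(i)] for i in fold]
        inner = split_dataset(
            [t.trial_id for t in rest], ratios=(0.85, 0.15, 0.0), seed=seed
        )
        model = fit_gait_model(
            rest, inner.train_ids, inner.validation_ids, channels, config
        )
        preds = predict_trials(model, held)
        targets = np.array([t.met_cost for t in held])
        m, r = _partition_metrics(preds, targets)
        fold_mse.append(m)
        fold_r.append(r)

    fold_mse_arr = np.array(fold_mse)
    finite_r = np.array([r for r in fold_r if not math.isnan(r)])
    return {
        "k": k,
        "fold_sizes": [len(f) for f in folds],
        "mse_mean": float(fold_mse_arr.mean()),
        "mse_sd": float(fold_mse_arr.std(ddof=1)),
        "r_mean": float(finite_r.mean()) if finite_r.size else math.nan,
        "r_sd": float(finite_r.std(ddof=1)) if finite_r.size > 1 else math.nan,
        "fold_mse": fold_mse,
        "fold_r": fold_r,
    }
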