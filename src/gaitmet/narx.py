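"""From-scratch NARX regression network trained with Levenberg-Marquardt.

The network is a nonlinear autoregressive model with exogenous inputs:
at step ``t`` it sees the current and ``d`` delayed values of each
exogenous channel plus ``q`` delayed values of the target, passes them
through one tanh hidden layer, and emits a linear output.  Training
runs in open-loop (series-parallel) mode -- the true delayed targets
fill the feedback taps -- with full-batch Levenberg-Marquardt and
validation-based early stopping.  Prediction for a whole gait trial
closes the loop: the feedback taps are filled with the model's own
previous outputs, seeded at the training-set mean target, and the
trial-level estimate is the mean of the per-step outputs after warm-up.

Per-trial scalar targets (one calorimetry value per trial) are bridged
to the time-series formulation by replicating the scalar across all
100 gait-cycle steps (:func:`trials_to_series`); the closed-loop
per-step predictions then hover around the trial's cost and their mean
recovers it.

Weight layout
-------------
All weights flatten to a single vector in the fixed order::

    W_in (hidden x P, row-major), b_hidden, W_out, b_out

where ``P = n_channels * (d + 1) + q``.  Within a regressor row the
columns are: for each channel (in order) its lags 0..d, then the
target lags 1..q.  The Jacobian's columns follow the same order.

Inputs and target are z-scored with training-set statistics before
regressor assembly; predictions are mapped back to physical units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    ConvergenceError,
    InvalidConfigError,
    NoDataError,
    NotFittedError,
    ShapeError,
)
from .synthetic import GaitTrial, SeriesSample

N_POINTS = 100

#: Channel sets of the two published model families.
GRF_CHANNELS = ("grf_ver", "grf_ap")
MOMENT_CHANNELS = ("hip_m", "knee_m", "ankle_m")


@dataclass
class NarxConfig:
    """Topology and training hyper-parameters of one NARX network.

    ``feedback_delays=None`` means "same as input_delays", matching the
    single delay count reported per model in the source toolbox.  The
    default trainer is full-batch Levenberg-Marquardt with the damping
    schedule mu <- mu*10 on rejection, mu <- mu*0.1 on acceptance; a
    literal mini-batch gradient trainer (batch 15, learning rate equal
    to ``mu_init``) is available via ``trainer="sgd"``.
    """

    hidden_size: int = 6
    input_delays: int = 2
    feedback_delays: int | None = None
    n_input_channels: int = 2
    max_epochs: int = 1000
    mu_init: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10
    max_validation_fail: int = 6
    seed: int = 0
    hidden_activation: str = "tanh"  # "identity" is a linear test hook
    trainer: str = "lm"  # or "sgd"
    batch_size: int = 15
    learning_rate: float = 1e-3
    #: sd of seeded Gaussian dither added to the (standardized) feedback
    #: taps during open-loop training; 0 disables.  With a constant
    #: replicated target the undithered feedback tap equals the target
    #: exactly, so the optimizer can satisfy the open-loop objective by
    #: copying it -- a solution that collapses in closed loop.  Dithering
    #: makes feedback weights cost what they are worth.
    feedback_dither: float = 0.1

    @property
    def fb_delays(self) -> int:
        return self.input_delays if self.feedback_delays is None else self.feedback_delays

    @property
    def warmup(self) -> int:
        return max(self.input_delays, self.fb_delays)

    @property
    def n_regressors(self) -> int:
        return self.n_input_channels * (self.input_delays + 1) + self.fb_delays

    def validate(self) -> None:
        if self.hidden_size < 1:
            raise InvalidConfigError("hidden_size must be >= 1")
        if self.input_delays < 1 or self.fb_delays < 1:
            raise InvalidConfigError("delays must be >= 1")
        if self.input_delays >= N_POINTS or self.fb_delays >= N_POINTS:
            raise InvalidConfigError(f"delays must be < {N_POINTS}")
        if self.n_input_channels < 1:
            raise InvalidConfigError("n_input_channels must be >= 1")
        if self.max_epochs < 1:
            raise InvalidConfigError("max_epochs must be >= 1")
        if self.mu_init <= 0:
            raise InvalidConfigError("mu_init must be > 0")
        if self.hidden_activation not in ("tanh", "identity"):
            raise InvalidConfigError("hidden_activation must be tanh or identity")
        if self.trainer not in ("lm", "sgd"):
            raise InvalidConfigError("trainer must be lm or sgd")
        if self.feedback_dither < 0:
            raise InvalidConfigError("feedback_dither must be >= 0")


@dataclass
class NarxModel:
    """A (possibly trained) NARX network: topology, weights, history."""

    config: NarxConfig
    W_in: np.ndarray
    b_hidden: np.ndarray
    W_out: np.ndarray
    b_out: float
    x_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    x_std: np.ndarray = field(default_factory=lambda: np.ones(0))
    y_mean: float = 0.0
    y_std: float = 1.0
    history: list[tuple[float, float]] = field(default_factory=list)
    channels: tuple[str, ...] | None = None
    fitted: bool = False

    @property
    def n_weights(self) -> int:
        h, p = self.W_in.shape
        return h * p + h + h + 1

    def get_weights(self) -> np.ndarray:
        return np.concatenate(
            [self.W_in.ravel(), self.b_hidden, self.W_out, [self.b_out]]
        )

    def set_weights(self, flat: np.ndarray) -> None:
        h, p = self.W_in.shape
        if flat.size != self.n_weights:
            raise ShapeError(f"expected {self.n_weights} weights, got {flat.size}")
        self.W_in = flat[: h * p].reshape(h, p)
        self.b_hidden = flat[h * p : h * p + h].copy()
        self.W_out = flat[h * p + h : h * p + 2 * h].copy()
        self.b_out = float(flat[-1])

    def to_dict(self) -> dict:
        return {
            "config": dataclasses.asdict(self.config),
            "weights": self.get_weights().tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "history": [list(h) for h in self.history],
            "channels": list(self.channels) if self.channels else None,
            "fitted": self.fitted,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NarxModel":
        config = NarxConfig(**d["config"])
        model = init_model(config)
        model.set_weights(np.asarray(d["weights"], dtype=float))
        model.x_mean = np.asarray(d["x_mean"], dtype=float)
        model.x_std = np.asarray(d["x_std"], dtype=float)
        model.y_mean = float(d["y_mean"])
        model.y_std = float(d["y_std"])
        model.history = [tuple(h) for h in d["history"]]
        model.channels = tuple(d["channels"]) if d.get("channels") else None
        model.fitted = bool(d["fitted"])
        return model


def init_model(config: NarxConfig) -> NarxModel:
    """Instantiate a model with seeded uniform(-0.5, 0.5) weights."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, p = config.hidden_size, config.n_regressors
    flat = rng.uniform(-0.5, 0.5, size=h * p + 2 * h + 1)
    model = NarxModel(
        config=config,
        W_in=np.zeros((h, p)),
        b_hidden=np.zeros(h),
        W_out=np.zeros(h),
        b_out=0.0,
    )
    model.set_weights(flat)
    return model


def assemble_regressors(
    trial_inputs: np.ndarray,
    target_series: np.ndarray,
    config: NarxConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Open-loop regressor matrix for one sample.

    One row per step ``t`` in ``{w..T-1}`` (0-based; ``w`` is the
    warm-up ``max(d, q)``): current and ``d`` delayed values of each
    exogenous channel, then the ``q`` delayed target values.  Returns
    ``(X, y)`` with ``y`` the target at those steps.
    """
    config.validate()
    x = np.atleast_2d(np.asarray(trial_inputs, dtype=float))
    y_full = np.asarray(target_series, dtype=float)
    n_ch, n_t = x.shape
    if n_ch != config.n_input_channels:
        raise ShapeError(
            f"expected {config.n_input_channels} channels, got {n_ch}"
        )
    if y_full.shape != (n_t,):
        raise ShapeError("target series length must match input length")
    d, q, w = config.input_delays, config.fb_delays, config.warmup
    if w >= n_t:
        raise InvalidConfigError(f"warm-up {w} leaves no usable steps of {n_t}")
    t_idx = np.arange(w, n_t)
    cols = []
    for ch in range(n_ch):
        for k in range(d + 1):
            cols.append(x[ch, t_idx - k])
    for k in range(1, q + 1):
        cols.append(y_full[t_idx - k])
    return np.column_stack(cols), y_full[t_idx]


def _activation(model: NarxModel, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if model.config.hidden_activation == "identity":
        return z, np.ones_like(z)
    h = np.tanh(z)
    return h, 1.0 - h * h


def forward(model: NarxModel, X: np.ndarray) -> np.ndarray:
    """Per-row network output ``W_out . act(W_in x + b_hidden) + b_out``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.W_in.shape[1]:
        raise ShapeError(
            f"X has {X.shape[1]} columns, model expects {model.W_in.shape[1]}"
        )
    h, _ = _activation(model, X @ model.W_in.T + model.b_hidden)
    return h @ model.W_out + model.b_out


def jacobian(model: NarxModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Jacobian ``J[i,k] = d e_i / d w_k`` of the residuals ``e = y - yhat``.

    Columns follow the flattened weight order (module docstring).  Since
    ``e`` depends on the weights only through ``-yhat``, every column is
    the negated output gradient; in particular the b_out column is -1
    everywhere.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    hsz = model.config.hidden_size
    z = X @ model.W_in.T + model.b_hidden
    h, hp = _activation(model, z)
    d_out = model.W_out * hp  # (n, hsz): d yhat / d z_j
    J = np.empty((n, model.n_weights))
    J[:, : hsz * p] = -(d_out[:, :, None] * X[:, None, :]).reshape(n, hsz * p)
    J[:, hsz * p : hsz * p + hsz] = -d_out
    J[:, hsz * p + hsz : hsz * p + 2 * hsz] = -h
    J[:, -1] = -1.0
    return J


def sse(model: NarxModel, X: np.ndarray, y: np.ndarray) -> float:
    e = y - forward(model, X)
    return float(e @ e)


def lm_step(
    model: NarxModel,
    X: np.ndarray,
    y: np.ndarray,
    mu: float,
) -> tuple[np.ndarray, float, bool]:
    """One damped Gauss-Newton trial step.

    Solves ``(J^T J + mu I) delta = J^T e`` and proposes
    ``w_candidate = w - delta`` (with ``J = d e/d w`` this is the
    descent direction; at large mu it reduces to a gradient step of
    size 1/mu).  If the candidate lowers the SSE it is accepted and mu
    shrinks by ``mu_decrease``; otherwise the weights stand and mu
    grows by ``mu_increase``.  Raises :class:`ConvergenceError` when mu
    already exceeds ``mu_max``.
    """
    if mu <= 0:
        raise InvalidConfigError("mu must be > 0")
    if mu > model.config.mu_max:
        raise ConvergenceError(f"damping mu={mu:g} exceeds mu_max")
    w0 = model.get_weights()
    e = y - forward(model, X)
    J = jacobian(model, X, y)
    A = J.T @ J + mu * np.eye(w0.size)
    g = J.T @ e
    delta = np.linalg.solve(A, g)
    candidate = w0 - delta
    sse_current = float(e @ e)
    model.set_weights(candidate)
    sse_candidate = sse(model, X, y)
    model.set_weights(w0)
    if sse_candidate < sse_current:
        return candidate, mu * model.config.mu_decrease, True
    return w0, mu * model.config.mu_increase, False


def trials_to_series(
    trials: Sequence[GaitTrial], channels: Sequence[str]
) -> list[SeriesSample]:
    """Map gait trials to NARX samples, replicating the scalar target."""
    return [
        SeriesSample(
            inputs=np.stack([t.waveform(ch) for ch in channels]),
            target=np.full(N_POINTS, t.met_cost),
        )
        for t in trials
    ]


def _standardize_inputs(model: NarxModel, inputs: np.ndarray) -> np.ndarray:
    return (inputs - model.x_mean[:, None]) / model.x_std[:, None]


def _pooled_regressors(
    model: NarxModel, samples: Sequence[SeriesSample]
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for s in samples:
        x_std = _standardize_inputs(model, np.asarray(s.inputs, dtype=float))
        y_std = (np.asarray(s.target, dtype=float) - model.y_mean) / model.y_std
        X, y = assemble_regressors(x_std, y_std, model.config)
        xs.append(X)
        ys.append(y)
    return np.vstack(xs), np.concatenate(ys)


def _train_lm(
    model: NarxModel, X_tr, y_tr, X_val, y_val
) -> None:
    # Same schedule as lm_step, but the Jacobian is computed once per
    # epoch and reused across damping retries.
    cfg = model.config
    mu = cfg.mu_init
    n_tr = y_tr.size
    best_val = np.inf
    best_w = model.get_weights()
    fails = 0
    eye = np.eye(model.n_weights)
    for _ in range(cfg.max_epochs):
        stopped = False
        w0 = model.get_weights()
        e = y_tr - forward(model, X_tr)
        J = jacobian(model, X_tr, y_tr)
        JtJ, g = J.T @ J, J.T @ e
        sse_current = float(e @ e)
        while True:
            if mu > cfg.mu_max:
                model.set_weights(w0)
                stopped = True
                break
            delta = np.linalg.solve(JtJ + mu * eye, g)
            model.set_weights(w0 - delta)
            if sse(model, X_tr, y_tr) < sse_current:
                mu *= cfg.mu_decrease
                break
            model.set_weights(w0)
            mu *= cfg.mu_increase
        train_mse = sse(model, X_tr, y_tr) / n_tr * model.y_std**2
        if X_val is not None:
            val_mse = sse(model, X_val, y_val) / y_val.size * model.y_std**2
        else:
            val_mse = train_mse
        model.history.append((train_mse, val_mse))
        if val_mse < best_val:
            best_val = val_mse
            best_w = model.get_weights()
            fails = 0
        else:
            fails += 1
        if stopped or fails >= cfg.max_validation_fail:
            break
    model.set_weights(best_w)


def _train_sgd(model: NarxModel, X_tr, y_tr, X_val, y_val) -> None:
    """Literal mini-batch gradient reading of the training recipe."""
    cfg = model.config
    rng = np.random.default_rng(cfg.seed + 1)
    n = y_tr.size
    best_val = np.inf
    best_w = model.get_weights()
    fails = 0
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Xb, yb = X_tr[idx], y_tr[idx]
            e = yb - forward(model, Xb)
            grad = jacobian(model, Xb, yb).T @ e  # d(SSE/2)/dw
            model.set_weights(model.get_weights() - cfg.learning_rate * grad)
        train_mse = sse(model, X_tr, y_tr) / n * model.y_std**2
        val_mse = (
            sse(model, X_val, y_val) / y_val.size * model.y_std**2
            if X_val is not None
            else train_mse
        )
        model.history.append((train_mse, val_mse))
        if val_mse < best_val:
            best_val, best_w, fails = val_mse, model.get_weights(), 0
        else:
            fails += 1
        if fails >= cfg.max_validation_fail:
            break
    model.set_weights(best_w)


def train(
    config: NarxConfig,
    train_samples: Sequence[SeriesSample],
    val_samples: Sequence[SeriesSample] = (),
    channels: Sequence[str] | None = None,
) -> NarxModel:
    """Train a NARX model in open-loop mode.

    Inputs and target are z-scored with training-set statistics; the
    pooled regressor matrix over all training samples is optimised by
    full-batch Levenberg-Marquardt (or mini-batch gradient descent when
    ``config.trainer == "sgd"``).  Seeded Gaussian dither of sd
    ``config.feedback_dither`` is added to the feedback taps of both
    matrices so that closed-loop deployment stays well-posed with
    replicated constant targets (see :class:`NarxConfig`).  Training stops at ``max_epochs``,
    when the damping exceeds ``mu_max``, or after
    ``max_validation_fail`` consecutive epochs without a new validation
    minimum; the returned weights are those of the epoch with minimum
    validation MSE.  History entries are per-epoch (train, validation)
    MSE in (W/kg)^2 (physical units).
    """
    config.validate()
    if len(train_samples) == 0:
        raise NoDataError("training set is empty")
    model = init_model(config)
    if channels is not None:
        model.channels = tuple(channels)

    inputs_all = np.concatenate(
        [np.atleast_2d(np.asarray(s.inputs, dtype=float)) for s in train_samples],
        axis=1,
    )
    model.x_mean = inputs_all.mean(axis=1)
    model.x_std = inputs_all.std(axis=1)
    model.x_std[model.x_std < 1e-12] = 1.0
    targets_all = np.concatenate([np.asarray(s.target, dtype=float) for s in train_samples])
    model.y_mean = float(targets_all.mean())
    model.y_std = float(targets_all.std())
    if model.y_std < 1e-12:
        model.y_std = 1.0

    X_tr, y_tr = _pooled_regressors(model, train_samples)
    if len(val_samples):
        X_val, y_val = _pooled_regressors(model, val_samples)
    else:
        X_val = y_val = None
    if config.feedback_dither > 0:
        q = config.fb_delays
        rng = np.random.default_rng(config.seed + 7919)
        X_tr[:, -q:] += rng.normal(0.0, config.feedback_dither, size=(X_tr.shape[0], q))
        if X_val is not None:
            X_val[:, -q:] += rng.normal(
                0.0, config.feedback_dither, size=(X_val.shape[0], q)
            )

    if config.trainer == "lm":
        _train_lm(model, X_tr, y_tr, X_val, y_val)
    else:
        _train_sgd(model, X_tr, y_tr, X_val, y_val)
    model.fitted = True
    return model


def predict_series_batch(model: NarxModel, inputs_batch: np.ndarray) -> np.ndarray:
    """Closed-loop trial-level predictions for a batch of input stacks.

    ``inputs_batch`` has shape (n_trials, n_channels, 100) in physical
    units.  The feedback taps are seeded with the training-set mean
    target (0 after standardization) and then filled with the model's
    own outputs step by step; the returned scalar per trial is the mean
    of the de-standardized per-step outputs over the post-warm-up steps.
    """
    if not model.fitted:
        raise NotFittedError("model must be trained before prediction")
    batch = np.asarray(inputs_batch, dtype=float)
    if batch.ndim == 2:
        batch = batch[None, :, :]
    n, n_ch, n_t = batch.shape
    cfg = model.config
    if n_ch != cfg.n_input_channels:
        raise ShapeError(f"expected {cfg.n_input_channels} channels, got {n_ch}")
    x = (batch - model.x_mean[None, :, None]) / model.x_std[None, :, None]
    d, q, w = cfg.input_delays, cfg.fb_delays, cfg.warmup
    yhat = np.zeros((n, n_t))  # standardized; 0 == training mean target
    for t in range(w, n_t):
        cols = [x[:, ch, t - k] for ch in range(n_ch) for k in range(d + 1)]
        cols += [yhat[:, t - k] for k in range(1, q + 1)]
        yhat[:, t] = forward(model, np.column_stack(cols))
    return model.y_mean + model.y_std * yhat[:, w:].mean(axis=1)


def predict_trial(model: NarxModel, trial: GaitTrial) -> float:
    """Closed-loop metabolic-cost prediction for one gait trial, W/kg."""
    if not model.fitted:
        raise NotFittedError("model must be trained before prediction")
    if model.channels is None:
        raise NotFittedError("model has no channel mapping; train via fit_gait_model")
    inputs = np.stack([trial.waveform(ch) for ch in model.channels])
    return float(predict_series_batch(model, inputs[None, :, :])[0])


def predict_trials(model: NarxModel, trials: Sequence[GaitTrial]) -> np.ndarray:
    """Vectorized closed-loop predictions for many trials, W/kg."""
    if model.channels is None:
        raise NotFittedError("model has no channel mapping; train via fit_gait_model")
    batch = np.stack(
        [np.stack([t.waveform(ch) for ch in model.channels]) for t in trials]
    )
    return predict_series_batch(model, batch)


def fit_gait_model(
    trials: Sequence[GaitTrial],
    train_ids: Sequence[str],
    val_ids: Sequence[str],
    channels: Sequence[str],
    config: NarxConfig,
) -> NarxModel:
    """Train a metabolic-cost model on the named partition of a cohort."""
    by_id = {t.trial_id: t for t in trials}
    train_samples = trials_to_series([by_id[i] for i in train_ids], channels)
    val_samples = trials_to_series([by_id[i] for i in val_ids], channels)
    cfg = dataclasses.replace(config, n_input_channels=len(channels))
    return train(cfg, train_samples, val_samples, channels=channels)
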