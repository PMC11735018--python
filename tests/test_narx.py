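"""Tests of the NARX core: regressors, forward pass, LM training."""

import dataclasses

import numpy as np
import pytest

import gaitmet as gm
from gaitmet.errors import (
    ConvergenceError,
    InvalidConfigError,
    NoDataError,
    NotFittedError,
    ShapeError,
)
from gaitmet.narx import (
    NarxConfig,
    assemble_regressors,
    forward,
    init_model,
    jacobian,
    lm_step,
    sse,
    train,
)
from gaitmet.synthetic import SeriesSample

from conftest import rng_model


def finite_difference_jacobian(model, X, y, h=1e-6):
    """Central finite-difference oracle for the residual Jacobian."""
    w0 = model.get_weights()
    J = np.zeros((len(y), w0.size))
    for k in range(w0.size):
        wp, wm = w0.copy(), w0.copy()
        wp[k] += h
        wm[k] -= h
        model.set_weights(wp)
        ep = y - forward(model, X)
        model.set_weights(wm)
        em = y - forward(model, X)
        J[:, k] = (ep - em) / (2 * h)
    model.set_weights(w0)
    return J


class TestAssembleRegressors:
    def test_tap_counts_d1_q1_two_channels(self):
        cfg = NarxConfig(input_delays=1, feedback_delays=1, n_input_channels=2)
        x = np.random.default_rng(0).normal(size=(2, 100))
        y = np.random.default_rng(1).normal(size=100)
        X, yt = assemble_regressors(x, y, cfg)
        assert X.shape == (99, 5)  # 2 ch x (current+1 lag) + 1 feedback
        assert yt.shape == (99,)

    def test_warmup_two_gives_98_rows(self):
        cfg = NarxConfig(input_delays=2, feedback_delays=2, n_input_channels=2)
        x = np.zeros((2, 100))
        X, _ = assemble_regressors(x, np.zeros(100), cfg)
        assert X.shape[0] == 98

    def test_constant_target_propagates_to_feedback_columns(self):
        cfg = NarxConfig(input_delays=1, feedback_delays=2, n_input_channels=1)
        x = np.random.default_rng(2).normal(size=(1, 100))
        X, _ = assemble_regressors(x, np.full(100, 3.3), cfg)
        np.testing.assert_array_equal(X[:, -2:], 3.3)

    def test_tap_values_match_series(self):
        cfg = NarxConfig(input_delays=2, feedback_delays=1, n_input_channels=1)
        x = np.arange(100.0)[None, :]
        y = 100.0 + np.arange(100.0)
        X, yt = assemble_regressors(x, y, cfg)
        # row 0 is step t=2: taps x[2], x[1], x[0], y[1]
        np.testing.assert_array_equal(X[0], [2.0, 1.0, 0.0, 101.0])
        assert yt[0] == 102.0

    def test_excessive_delay_rejected(self):
        cfg = NarxConfig(input_delays=150, n_input_channels=1)
        with pytest.raises(InvalidConfigError):
            assemble_regressors(np.zeros((1, 100)), np.zeros(100), cfg)


class TestForward:
    def test_bias_only_network(self):
        model = rng_model(0)
        model.set_weights(np.zeros(model.n_weights))
        model.b_out = 1.7
        X = np.random.default_rng(3).normal(size=(8, model.W_in.shape[1]))
        np.testing.assert_allclose(forward(model, X), 1.7, atol=0)

    def test_hand_computed_single_unit(self):
        cfg = NarxConfig(hidden_size=1, input_delays=1, n_input_channels=1)
        model = init_model(cfg)
        model.W_in = np.array([[0.5, -0.25, 0.1]])
        model.b_hidden = np.array([0.2])
        model.W_out = np.array([2.0])
        model.b_out = -1.0
        x = np.array([[1.0, 2.0, 3.0]])
        expected = 2.0 * np.tanh(0.5 * 1 - 0.25 * 2 + 0.1 * 3 + 0.2) - 1.0
        assert forward(model, x)[0] == pytest.approx(expected, abs=1e-14)

    def test_output_scaling_linearity(self):
        model = rng_model(4)
        model.b_out = 0.0
        X = np.random.default_rng(5).normal(size=(10, model.W_in.shape[1]))
        base = forward(model, X)
        model.W_out = 2 * model.W_out
        np.testing.assert_allclose(forward(model, X), 2 * base, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        model = rng_model(6)
        with pytest.raises(ShapeError):
            forward(model, np.zeros((3, model.W_in.shape[1] + 1)))


class TestJacobian:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        model = rng_model(seed, hidden=3, delays=1, n_channels=2)
        X = rng.normal(size=(12, model.W_in.shape[1]))
        y = rng.normal(size=12)
        J = jacobian(model, X, y)
        J_fd = finite_difference_jacobian(model, X, y)
        denom = np.maximum(np.abs(J_fd), 1e-8)
        assert np.max(np.abs(J - J_fd) / denom) < 1e-5

    def test_identity_activation_output_weight_block(self):
        model = rng_model(1, activation="identity")
        rng = np.random.default_rng(7)
        X = rng.normal(size=(9, model.W_in.shape[1]))
        y = rng.normal(size=9)
        J = jacobian(model, X, y)
        h, p = model.W_in.shape
        # with identity activation the output-weight columns are -(W_in x + b)
        np.testing.assert_allclose(
            J[:, h * p + h : h * p + 2 * h],
            -(X @ model.W_in.T + model.b_hidden),
            atol=1e-12,
        )

    def test_output_bias_column_is_minus_one(self):
        model = rng_model(2)
        X = np.zeros((5, model.W_in.shape[1]))
        J = jacobian(model, X, np.zeros(5))
        np.testing.assert_array_equal(J[:, -1], -1.0)


class TestLmStep:
    def test_small_mu_matches_direct_least_squares_solve(
        self, rand_regression_problem
    ):
        # at mu -> 0 the step is the Gauss-Newton solution of the
        # linearized residual system J delta = e, so it must agree with
        # a direct least-squares solve of that system.
        X, y = rand_regression_problem(0, n_rows=60, n_cols=3)
        model = rng_model(0, hidden=2, delays=1, n_channels=1,
                          activation="identity")
        e = y - forward(model, X)
        J = jacobian(model, X, y)
        delta_ls, *_ = np.linalg.lstsq(J, -e, rcond=None)
        w0 = model.get_weights()
        w, _, accepted = lm_step(model, X, y, mu=1e-9)
        assert accepted
        # the identity-activation parametrization is degenerate (J has a
        # null space), so compare in fitted-value space, which is unique
        np.testing.assert_allclose(J @ (w - w0), J @ delta_ls, atol=1e-6)

    def test_iterated_lm_reaches_linear_model_optimum(
        self, rand_regression_problem
    ):
        # with the identity activation the network spans exactly the
        # affine predictors of x, so LM must drive the SSE down to the
        # closed-form normal-equations optimum on the basis [X, 1].
        X, y = rand_regression_problem(1, n_rows=60, n_cols=3)
        model = rng_model(1, hidden=2, delays=1, n_channels=1,
                          activation="identity")
        full_basis = np.column_stack([X, np.ones(60)])
        beta, *_ = np.linalg.lstsq(full_basis, y, rcond=None)
        best_possible = float(np.sum((y - full_basis @ beta) ** 2))
        mu = 1e-3
        for _ in range(100):
            try:
                w, mu, accepted = lm_step(model, X, y, mu)
            except ConvergenceError:
                break
            if accepted:
                model.set_weights(w)
        assert sse(model, X, y) == pytest.approx(best_possible, rel=1e-6, abs=1e-9)

    def test_large_mu_is_small_gradient_step(self):
        model = rng_model(3)
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, model.W_in.shape[1]))
        y = rng.normal(size=20)
        mu = 1e8
        e = y - forward(model, X)
        J = jacobian(model, X, y)
        expected_delta = (J.T @ e) / mu
        w0 = model.get_weights()
        w, _, _ = lm_step(model, X, y, mu=mu)
        np.testing.assert_allclose(w, w0 - expected_delta, atol=1e-10)

    def test_rejection_contract(self):
        model = rng_model(5)
        rng = np.random.default_rng(9)
        X = rng.normal(size=(15, model.W_in.shape[1]))
        y = forward(model, X)  # already at zero error: any step is worse
        w0 = model.get_weights()
        w, mu, accepted = lm_step(model, X, y, mu=1.0)
        assert not accepted
        assert mu == 10.0
        np.testing.assert_array_equal(w, w0)

    def test_mu_ceiling_raises(self):
        model = rng_model(6)
        X = np.zeros((5, model.W_in.shape[1]))
        with pytest.raises(ConvergenceError):
            lm_step(model, X, np.zeros(5), mu=1e11)


def _linear_series_samples(n, seed, noise=0.0):
    """Targets that are an exact linear function of the exogenous taps."""
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n):
        x = rng.normal(size=(1, 100))
        y = np.empty(100)
        y[0] = 0.0
        y[1:] = 0.4 * x[0, 1:] - 0.7 * x[0, :-1]
        if noise:
            y += rng.normal(0, noise, size=100)
        samples.append(SeriesSample(inputs=x, target=y))
    return samples


class TestTrain:
    def test_recovers_realizable_linear_function(self):
        cfg = NarxConfig(
            hidden_size=3,
            input_delays=1,
            n_input_channels=1,
            max_epochs=300,
            seed=1,
            feedback_dither=0.0,
        )
        samples = _linear_series_samples(8, seed=10)
        model = train(cfg, samples[:6], samples[6:])
        assert model.history[-1][0] < 1e-6

    def test_epoch_cap(self):
        cfg = NarxConfig(
            hidden_size=2, input_delays=1, n_input_channels=1, max_epochs=1, seed=0
        )
        model = train(cfg, _linear_series_samples(3, seed=11))
        assert len(model.history) == 1

    def test_early_stopping_patience(self):
        # validation target unrelated to inputs: val error rises as the
        # model fits the training data, tripping the patience counter.
        rng = np.random.default_rng(12)
        cfg = NarxConfig(
            hidden_size=4,
            input_delays=1,
            n_input_channels=1,
            max_epochs=500,
            max_validation_fail=6,
            seed=2,
            feedback_dither=0.0,
        )
        train_s = _linear_series_samples(6, seed=13)
        val_s = [
            SeriesSample(inputs=rng.normal(size=(1, 100)), target=rng.normal(size=100))
            for _ in range(2)
        ]
        model = train(cfg, train_s, val_s)
        assert len(model.history) < 500
        vals = [v for _, v in model.history]
        best_epoch = int(np.argmin(vals))
        assert len(vals) - 1 - best_epoch >= 6

    def test_accepted_steps_never_increase_training_sse(self):
        cfg = NarxConfig(
            hidden_size=4,
            input_delays=2,
            n_input_channels=1,
            max_epochs=80,
            seed=3,
        )
        samples = _linear_series_samples(6, seed=14, noise=0.05)
        model = train(cfg, samples[:5], samples[5:])
        train_curve = np.array([t for t, _ in model.history])
        assert np.all(np.diff(train_curve) <= 1e-12)

    def test_seeded_determinism(self):
        cfg = NarxConfig(
            hidden_size=3, input_delays=1, n_input_channels=1, max_epochs=30, seed=7
        )
        samples = _linear_series_samples(5, seed=15, noise=0.1)
        m1 = train(cfg, samples[:4], samples[4:])
        m2 = train(dataclasses.replace(cfg), samples[:4], samples[4:])
        np.testing.assert_array_equal(m1.get_weights(), m2.get_weights())
        assert m1.history == m2.history

    def test_empty_training_set_rejected(self):
        with pytest.raises(NoDataError):
            train(NarxConfig(n_input_channels=1), [])

    def test_sgd_trainer_reduces_error(self):
        cfg = NarxConfig(
            hidden_size=3,
            input_delays=1,
            n_input_channels=1,
            max_epochs=40,
            seed=4,
            trainer="sgd",
            learning_rate=1e-3,
            batch_size=15,
            feedback_dither=0.0,
        )
        samples = _linear_series_samples(5, seed=16)
        model = train(cfg, samples[:4], samples[4:])
        assert model.history[-1][0] < model.history[0][0]


class TestPrediction:
    def test_bias_only_model_predicts_constant(self, small_cohort):
        cfg = NarxConfig(hidden_size=2, input_delays=1, n_input_channels=2)
        model = init_model(cfg)
        model.set_weights(np.zeros(model.n_weights))
        model.b_out = 3.5
        model.x_mean = np.zeros(2)
        model.x_std = np.ones(2)
        model.y_mean, model.y_std = 0.0, 1.0
        model.channels = gm.GRF_CHANNELS
        model.fitted = True
        for t in small_cohort[:3]:
            assert gm.predict_trial(model, t) == pytest.approx(3.5, abs=1e-12)

    def test_identical_trials_identical_predictions(self, small_cohort):
        split = gm.split_dataset([t.trial_id for t in small_cohort], seed=0)
        cfg = NarxConfig(hidden_size=3, input_delays=1, max_epochs=30, seed=0)
        model = gm.fit_gait_model(
            small_cohort, split.train_ids, split.validation_ids, gm.GRF_CHANNELS, cfg
        )
        t = small_cohort[0]
        assert gm.predict_trial(model, t) == gm.predict_trial(model, t)

    def test_unfitted_model_rejected(self, small_cohort):
        model = init_model(NarxConfig(n_input_channels=2))
        model.channels = gm.GRF_CHANNELS
        with pytest.raises(NotFittedError):
            gm.predict_trial(model, small_cohort[0])


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, small_cohort, tmp_path):
        from gaitmet.io import read_model_json, write_model_json

        split = gm.split_dataset([t.trial_id for t in small_cohort], seed=0)
        cfg = NarxConfig(hidden_size=3, input_delays=2, max_epochs=20, seed=5)
        model = gm.fit_gait_model(
            small_cohort, split.train_ids, split.validation_ids, gm.GRF_CHANNELS, cfg
        )
        path = tmp_path / "model.json"
        write_model_json(model, path)
        loaded = read_model_json(path)
        preds0 = gm.predict_trials(model, small_cohort)
        preds1 = gm.predict_trials(loaded, small_cohort)
        np.testing.assert_array_equal(preds0, preds1)
        assert loaded.history == model.history
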