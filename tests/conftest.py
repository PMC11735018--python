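import numpy as np
import pytest

import gaitmet as gm


def zero_noise_channels():
    return {ch: 0.0 for ch in gm.CHANNELS}


@pytest.fixture(scope="session")
def default_cohort():
    """The full 270-trial cohort at default design settings."""
    return gm.generate_cohort(gm.CohortDesign(seed=7))


@pytest.fixture(scope="session")
def noiseless_design():
    """Default layout with all noise removed; heterogeneity retained."""
    return gm.CohortDesign(
        cost_noise_sd=0.0, measurement_noise_sd=zero_noise_channels(), seed=3
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_design):
    return gm.generate_cohort(noiseless_design)


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-trial single-study cohort for cheap end-to-end checks."""
    design = gm.CohortDesign(studies=(("mini", 4, 6),), seed=11)
    return gm.generate_cohort(design)


@pytest.fixture(scope="session")
def trained_grf_model(noiseless_cohort):
    """GRF-channel model trained to convergence on the noiseless cohort."""
    split = gm.split_dataset([t.trial_id for t in noiseless_cohort], seed=1)
    cfg = gm.NarxConfig(hidden_size=6, input_delays=2, max_epochs=400, seed=0)
    model = gm.fit_gait_model(
        noiseless_cohort, split.train_ids, split.validation_ids, gm.GRF_CHANNELS, cfg
    )
    return model, split


def rng_model(seed, hidden=3, delays=1, n_channels=2, activation="tanh"):
    """A small randomly initialized model for gradient checks."""
    from gaitmet.narx import NarxConfig, init_model

    cfg = NarxConfig(
        hidden_size=hidden,
        input_delays=delays,
        n_input_channels=n_channels,
        seed=seed,
        hidden_activation=activation,
    )
    return init_model(cfg)


@pytest.fixture
def rand_regression_problem():
    def make(seed, n_rows=40, n_cols=5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n_rows, n_cols))
        y = rng.normal(size=n_rows)
        return X, y

    return make
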