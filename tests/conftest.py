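import warnings

import numpy as np
import pytest

import groomnet as gn
from groomnet.saom import SAOM

warnings.filterwarnings("ignore", category=UserWarning)

RECOVERY_TRUE_BETA = {"outdegree": -2.0, "reciprocity": 1.2}
RECOVERY_TRUE_RATE = 5.0
RECOVERY_N = 30
RECOVERY_DENSITY = 0.25


def make_recovery_panel(seed: int):
    """Panel of 6 waves on 30 actors from the known two-effect model."""
    cfg = gn.SynthConfig(
        n_actors=RECOVERY_N,
        entry_schedule=(RECOVERY_N, 0, 0, 0, 0, 0),
        beta_true=dict(RECOVERY_TRUE_BETA),
        rate_true=RECOVERY_TRUE_RATE,
        initial_density=RECOVERY_DENSITY,
        seed=seed,
    )
    actors = gn.gen_cohort(cfg)
    spec = gn.build_model_spec(cfg.beta_true, cfg.rates, actors)
    panel = gn.gen_wave_panel(actors, spec, seed=seed * 7 + 1,
                              initial_density=RECOVERY_DENSITY)
    return actors, spec, panel


def fit_recovery_panel(actors, panel, seed: int, **options) -> SAOM:
    fit_spec = gn.build_model_spec(
        {"outdegree": 0.0, "reciprocity": 0.0},
        [1.0] * (panel.n_waves - 1), actors,
    )
    options.setdefault("n3", 500)
    model = SAOM(spec=fit_spec, seed=seed, **options)
    model.fit(panel)
    return model


@pytest.fixture(scope="session")
def recovery_fit():
    """One converged fit on a known-truth panel, shared across tests."""
    actors, spec, panel = make_recovery_panel(3)
    model = fit_recovery_panel(actors, panel, seed=103)
    return actors, spec, panel, model


@pytest.fixture(scope="session")
def paper_study():
    """Default synthetic herd mirroring the study conditions."""
    return gn.generate_study(gn.SynthConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
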