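"""Shared fixtures: the canonical parameterization, its steady states and
one synthetic adequate-diet dataset, cached per session because the
lead-in and tracer simulations behind them are reused by many tests."""

import numpy as np
import pytest

import ferrokin as fk
from ferrokin.protocols import steady_state, tracer_experiment


@pytest.fixture(scope="session")
def params6() -> fk.ParameterSet:
    """The canonical adequate-diet parameter set (published column #6)."""
    return fk.fixture_table2(6)


@pytest.fixture(scope="session")
def plain_model(params6):
    return fk.build_model(params6, include_tracer=False)


@pytest.fixture(scope="session")
def tracer_model(params6):
    return fk.build_model(params6, include_tracer=True)


@pytest.fixture(scope="session")
def adequate_ss(plain_model):
    """Adequate-diet steady state of the tracer-free model."""
    return steady_state(plain_model)


@pytest.fixture(scope="session")
def tracer_traj(params6):
    """Tracer experiment on a dense 28-day grid (set #6, adequate diet)."""
    times = np.concatenate(([0.0], np.geomspace(1e-3, 28.0, 400)))
    return tracer_experiment(params6, observation_days=times)


@pytest.fixture(scope="session")
def adequate_dataset(params6):
    """Synthetic adequate-diet dataset, 5% proportional noise."""
    return fk.generate(params6, noise_cv=0.05, seed=42)


@pytest.fixture(scope="session")
def noiseless_dataset(params6):
    return fk.generate(params6, noise_cv=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
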