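"""Shared fixtures.

Expensive simulations (the aggressive treated/untreated pair and the
kinetics sweep, both on the half-resolution 2 mm phantom) are session-scoped
so the behavioral tests share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

import edemasim as es


@pytest.fixture(scope="session")
def test_config() -> es.ExperimentConfig:
    """Half-resolution (2 mm) configuration used by the behavioral tests."""
    return es.ExperimentConfig(nx=74, ny=93, spacing=2.0)


@pytest.fixture(scope="session")
def phantom(test_config) -> es.TissueMap:
    return test_config.phantom()


@pytest.fixture(scope="session")
def default_params() -> es.ModelParameters:
    return es.ModelParameters()


@pytest.fixture(scope="session")
def aggressive_pair(test_config):
    """Treated and matched untreated aggressive-case runs (rho=75 /yr,
    D_w=53, D_g=0.53 mm^2/yr) plus the pair summary."""
    series_t, series_u, summary = es.run_pair(75.0, 53.0, 0.53,
                                              config=test_config)
    return series_t, series_u, summary


@pytest.fixture(scope="session")
def untreated_aggressive(test_config):
    """Standalone untreated aggressive run ending at the boundary rule."""
    _, series, summary = es.run_case(75.0, 53.0, 0.53, treated=False,
                                     config=test_config)
    return series, summary


@pytest.fixture(scope="session")
def sweep_table(test_config):
    """The six-scenario kinetics sweep on the 2 mm phantom."""
    return es.run_sweep(es.SweepSpec(), test_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_state(rng, shape=(5, 5), a_scale=5e-6) -> es.StateFields:
    """A random valid state: cell fractions summing below capacity."""
    raw = rng.uniform(0.0, 1.0, size=(4,) + shape)
    raw /= np.maximum(raw.sum(axis=0), 1.0)[None]
    state = es.StateFields(
        c=raw[0], h=raw[1], n=raw[2], v=raw[3],
        a=rng.uniform(0.0, a_scale, size=shape),
        l=rng.uniform(0.0, 1.0, size=shape),
    )
    return state
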