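"""Shared fixtures: parameter sets and full-length simulation runs that
several test modules analyse (session-scoped so each runs once)."""

import pytest

from chaostrench import default_parameters
from chaostrench.simulator import SimulationConfig, run_single


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def run_fluctuating_100(params):
    """Full-model run at 100 uM (the correlation-dimension condition)."""
    cfg = SimulationConfig(duration=5250, h_treatment=100.0, rng_seed=1)
    return run_single(cfg, params)


@pytest.fixture(scope="session")
def run_no_growth(params):
    """S+I ablation: elongation rate pinned at g0 (strictly periodic)."""
    cfg = SimulationConfig(duration=5250, h_treatment=80.0, coupling="S+I",
                           rng_seed=1)
    return run_single(cfg, params)
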