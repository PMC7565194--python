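"""Shared fixtures: small synthetic sections rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from cycifpipe.synthetic import (
    SimulationConfig,
    default_panel,
    generate_ground_truth,
    render_cycles,
)

SMALL_TRANSFORMS = [
    (0.0, 0.0, 0.0, 1.0),
    (6.0, -4.0, 0.5, 1.0),
    (-5.0, 3.0, -1.0, 1.01),
    (2.0, 7.0, 1.5, 0.99),
    (-7.0, -5.0, 0.8, 1.0),
]


def small_sim_config(**overrides) -> SimulationConfig:
    defaults = dict(
        image_shape=(256, 256),
        n_cells=50,
        margin_px=32.0,
        rng_seed=7,
        cycle_transforms=[tuple(t) for t in SMALL_TRANSFORMS],
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def small_panel(small_config):
    return default_panel(small_config)


@pytest.fixture(scope="session")
def small_gt(small_config):
    return generate_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_cycles(small_gt, small_config, small_panel):
    return render_cycles(small_gt, small_config, small_panel)


@pytest.fixture(scope="session")
def noiseless_config():
    return small_sim_config(noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_gt(noiseless_config):
    return generate_ground_truth(noiseless_config)


@pytest.fixture(scope="session")
def noiseless_cycles(noiseless_gt, noiseless_config, small_panel):
    return render_cycles(noiseless_gt, noiseless_config, small_panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
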