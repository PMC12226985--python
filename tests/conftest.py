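"""Shared fixtures: deterministic synthetic recordings and cohorts.

The standing test input is the simulator's 8-channel, 10 s, seed-0 patient;
everything is generated at test time so the suite needs no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from neurofragility.config import RunConfig
from neurofragility.synthetic_data import CohortConfig, SimulationConfig, build_fragile_network, simulate_cohort, simulate_recording


@pytest.fixture(scope="session")
def sim_cfg() -> SimulationConfig:
    """Standing simulator settings: 8 channels, 10 s, seed 0, fragile {0, 1}."""
    return SimulationConfig(
        n_channels=8,
        fs=2000.0,
        duration_s=10.0,
        fragile_set=(0, 1),
        seed=0,
        cohort=CohortConfig(n_patients=6, success_fraction=1.0),
    )


@pytest.fixture(scope="session")
def fixture_network(sim_cfg):
    return build_fragile_network(sim_cfg)


@pytest.fixture(scope="session")
def fixture_patient(sim_cfg, fixture_network):
    """The standing synthetic patient: (SeegRecording, ChannelAnnotation)."""
    A, _ = fixture_network
    rng = np.random.default_rng(sim_cfg.seed)
    return simulate_recording(sim_cfg, A_true=A, rng=rng)


@pytest.fixture(scope="session")
def success_cohort(sim_cfg):
    """A small all-success cohort (6 patients, 10 s each)."""
    return simulate_cohort(sim_cfg)


@pytest.fixture(scope="session")
def mixed_cohort():
    """A mixed-outcome cohort: 8 patients, 6 success / 2 failure."""
    cfg = SimulationConfig(
        n_channels=8,
        duration_s=10.0,
        fragile_set=(0, 1),
        seed=11,
        cohort=CohortConfig(n_patients=8, success_fraction=0.75),
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def run_config() -> RunConfig:
    cfg = RunConfig()
    cfg.classifier.n_trees = 100  # plenty for 7-feature problems; keeps tests quick
    return cfg
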