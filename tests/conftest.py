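"""Shared fixtures: small grids, synthetic cohorts, and one full study run."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from expocube import (
    StudyConfig,
    SynthScenario,
    make_outlets,
    make_trajectories,
    preprocess_all,
)
from expocube.io import OutletRegistry
from expocube.preprocess import Trajectory, flag_valid_days


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    """Small, fast grid: 1.2 km extent divisible by all three cell sizes."""
    return StudyConfig(grid_extent=(0.0, 0.0, 1200.0, 1200.0))


@pytest.fixture(scope="session")
def default_config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def scenario(config) -> SynthScenario:
    return SynthScenario(n_participants=3, n_outlets=25, seed=7)


@pytest.fixture(scope="session")
def registry(scenario, config) -> OutletRegistry:
    return make_outlets(scenario, config)


@pytest.fixture(scope="session")
def trajectories(scenario, config):
    raw = make_trajectories(scenario, config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return preprocess_all(raw)


def make_day_trajectory(pid: str, date: str, positions: np.ndarray,
                        minutes: np.ndarray | None = None) -> Trajectory:
    """Trajectory covering one local date at given per-minute positions."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if minutes is None:
        minutes = np.arange(n)
    ts = pd.Timestamp(date) + pd.to_timedelta(minutes, unit="min")
    raw = pd.DataFrame(
        {"timestamp": ts, "x": positions[:, 0], "y": positions[:, 1]}
    )
    return flag_valid_days(Trajectory.from_raw(pid, raw))


@pytest.fixture(scope="session")
def full_study():
    """One end-to-end study at the default scale (46 participants, 54 cubes).

    Session-scoped: the exposure table is reused by the design-count and
    model-discrimination checks.
    """
    from expocube.pipeline import run_synthetic_study

    cfg = StudyConfig()
    scen = SynthScenario(seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return scen, cfg, run_synthetic_study(scen, cfg)
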