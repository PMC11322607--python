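"""Shared fixtures: small synthetic scenes kept cheap enough for unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from tumotrack import (
    AssayScenario,
    KillingParams,
    MotilityParams,
    RenderParams,
)
from tumotrack.synthetic import GroundTruth
from tumotrack.tracking import Trajectory


@pytest.fixture
def small_scenario() -> AssayScenario:
    """A fast 200×200×120 µm scenario with a 50 µm tumoroid."""
    return AssayScenario(
        volume_size=(200.0, 200.0, 120.0),
        tumoroid_center=(100.0, 100.0, 60.0),
        tumoroid_radius=50.0,
        n_nuclei=80,
        n_tcells=20,
        n_seed_contact=3,
        n_frames=8,
        seed=7,
    )


@pytest.fixture
def noise_free_render() -> RenderParams:
    return RenderParams(poisson_noise=False)


def grid_trajectories(n_x: int, n_y: int, n_frames: int, spacing: float,
                      step_sigma: float, z0: float, seed: int) -> list[Trajectory]:
    """Well-separated cells on a lateral grid taking small Gaussian steps."""
    rng = np.random.default_rng(seed)
    trajs = []
    cell = 0
    times = np.arange(n_frames, dtype=float)
    for i in range(n_x):
        for j in range(n_y):
            start = np.array([(i + 1) * spacing, (j + 1) * spacing, z0])
            steps = rng.normal(0.0, step_sigma, size=(n_frames - 1, 3))
            pos = np.vstack([start, start + np.cumsum(steps, axis=0)])
            trajs.append(Trajectory(cell_id=cell, times=times.copy(),
                                    positions=pos))
            cell += 1
    return trajs


def ground_truth_from_trajectories(trajs: list[Trajectory],
                                   nuclei: np.ndarray | None = None,
                                   death_times: np.ndarray | None = None,
                                   pi_onset_delay: float = 0.0) -> GroundTruth:
    nuclei = np.empty((0, 3)) if nuclei is None else nuclei
    if death_times is None:
        death_times = np.full(len(nuclei), np.nan)
    return GroundTruth(
        nucleus_positions=nuclei,
        death_times=death_times,
        trajectories=trajs,
        phase_switch_times=np.full(len(trajs), np.nan),
        pi_onset_delay=pi_onset_delay)


@pytest.fixture
def diffusion_free_scenario() -> tuple[AssayScenario, MotilityParams, KillingParams]:
    """Ballistic setup: zero diffusion, constant drift toward the tumoroid."""
    scenario = AssayScenario(
        volume_size=(400.0, 400.0, 400.0),
        tumoroid_center=(200.0, 200.0, 200.0),
        n_nuclei=5,
        n_tcells=1,
        n_seed_contact=0,
        n_frames=11,
        seed=3,
    )
    motility = MotilityParams(d_axis=0.0, speed=3.0, switch_mode="always",
                              sensing_radius=1e6)
    killing = KillingParams(kill_rate_per_contact=0.0)
    return scenario, motility, killing
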