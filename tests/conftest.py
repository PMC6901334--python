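"""Shared fixtures: small sheets for dynamics tests, synthetic records."""

from __future__ import annotations

import numpy as np
import pytest

from gridwave.config import BehavioralState, SimulationConfig
from gridwave.simulator import SpikeRecord
from gridwave.trajectory import Trajectory


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A 64-neuron sheet: full dynamics, cheap steps."""
    return SimulationConfig(n=64)


@pytest.fixture()
def quiet_small_config() -> SimulationConfig:
    """Small sheet with noise disabled, for exact-arithmetic oracles."""
    return SimulationConfig(n=64, noise_var_exc=0.0, noise_var_inh=0.0)


def make_track_trajectory(
    n_steps: int = 4000,
    track_length: float = 100.0,
    speed: float = 0.5,
    dt: float = 1.0,
    n_laps: int = 2,
    idle_steps: int = 500,
) -> Trajectory:
    """Deterministic constant-speed track trajectory for analysis tests."""
    pos_parts, vel_parts, state_parts, lap_parts, dir_parts = [], [], [], [], []
    run_steps = int(track_length / (speed * dt * 0.1))
    current = 0.0
    for lap in range(n_laps):
        d = 1 if lap % 2 == 0 else -1
        pos_parts.append(np.full(idle_steps, current))
        vel_parts.append(np.zeros((idle_steps, 2)))
        state_parts.append(np.full(idle_steps, int(BehavioralState.IDLE), np.uint8))
        lap_parts.append(np.full(idle_steps, -1, np.int32))
        dir_parts.append(np.zeros(idle_steps, np.int8))
        p = current + d * np.arange(1, run_steps + 1) * speed * dt * 0.1
        pos_parts.append(p)
        vel_parts.append(np.tile([d * speed, 0.0], (run_steps, 1)))
        state_parts.append(np.full(run_steps, int(BehavioralState.RUN), np.uint8))
        lap_parts.append(np.full(run_steps, lap, np.int32))
        dir_parts.append(np.full(run_steps, d, np.int8))
        current = p[-1]
    return Trajectory(
        dt=dt,
        pos=np.concatenate(pos_parts),
        vel=np.concatenate(vel_parts),
        state=np.concatenate(state_parts),
        lap_index=np.concatenate(lap_parts),
        direction=np.concatenate(dir_parts),
        track_length_cm=track_length,
        is_1d=True,
        psi0=np.zeros(n_laps),
    )


def make_record(
    pops: np.ndarray,
    ys: np.ndarray,
    xs: np.ndarray,
    steps: np.ndarray,
    trajectory: Trajectory,
    f_theta: float = 8.0,
) -> SpikeRecord:
    """SpikeRecord wrapper around explicit event arrays."""
    order = np.argsort(steps)
    t_s = np.arange(trajectory.n_steps) * trajectory.dt / 1000.0
    drive = np.where(
        trajectory.run_mask(),
        0.72 - 0.2 * np.cos(2 * np.pi * f_theta * t_s),
        0.0,
    ).astype(np.float32)
    return SpikeRecord(
        dt=trajectory.dt,
        pop=np.asarray(pops, np.uint8)[order],
        y=np.asarray(ys, np.uint16)[order],
        x=np.asarray(xs, np.uint16)[order],
        step=np.asarray(steps, np.int64)[order],
        drive_trace=drive,
        trajectory=trajectory,
    )
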