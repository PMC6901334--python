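"""Animal trajectories: 1D track sessions and 2D open-field paths.

Track sessions alternate end-to-end runs with idle periods; a brief
allocentric-correction pulse separates each idle period from the following
run.  Running speed fluctuates around a target value following a fractional
Brownian motion profile, mimicking naturalistic speed variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BehavioralState, SimulationConfig
from .kernels import SPATIAL_DIRECTIONS, POPULATIONS

__all__ = [
    "Trajectory",
    "fractional_gaussian_noise",
    "generate_open_field_trajectory",
    "generate_track_trajectory",
    "velocity_drive_factor",
]


@dataclass
class Trajectory:
    """Time series of position, velocity, and behavioral state on the dt grid.

    ``pos`` is the scalar track coordinate in cm for 1D sessions or an
    (T, 2) array of arena coordinates for open-field paths.  ``vel`` is
    always an (T, 2) array in m/s (the 1D track is embedded in the plane at
    ``track_angle_deg``).  ``lap_index`` is -1 outside run segments;
    ``direction`` is +1 for rightward laps, -1 leftward, 0 otherwise.
    """

    dt: float                      # ms
    pos: np.ndarray                # cm
    vel: np.ndarray                # m/s, shape (T, 2)
    state: np.ndarray              # uint8 BehavioralState codes
    lap_index: np.ndarray          # int32
    direction: np.ndarray          # int8
    track_length_cm: float = 100.0
    is_1d: bool = True
    psi0: np.ndarray = field(default_factory=lambda: np.zeros(0))  # per-lap theta offset

    @property
    def n_steps(self) -> int:
        return len(self.state)

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    @property
    def n_laps(self) -> int:
        return int(self.lap_index.max()) + 1 if self.lap_index.size else 0

    def run_mask(self) -> np.ndarray:
        return self.state == int(BehavioralState.RUN)

    def idle_mask(self) -> np.ndarray:
        return self.state == int(BehavioralState.IDLE)

    def speed(self) -> np.ndarray:
        return np.sqrt((self.vel ** 2).sum(axis=1))

    def mean_run_speed(self) -> float:
        m = self.run_mask()
        return float(self.speed()[m].mean()) if m.any() else float("nan")

    def reversed(self) -> "Trajectory":
        """Same session with reversed run velocities (mirrored positions)."""
        if not self.is_1d:
            raise ValueError("reversal is defined for 1D track sessions")
        out = Trajectory(
            dt=self.dt,
            pos=self.track_length_cm - self.pos,
            vel=-self.vel,
            state=self.state.copy(),
            lap_index=self.lap_index.copy(),
            direction=-self.direction,
            track_length_cm=self.track_length_cm,
            is_1d=True,
            psi0=self.psi0.copy(),
        )
        return out

    def to_frame(self) -> pd.DataFrame:
        pos = np.atleast_2d(self.pos.T).T
        x = pos[:, 0]
        y = pos[:, 1] if pos.shape[1] > 1 else np.zeros_like(x)
        return pd.DataFrame({
            "t_ms": self.t_ms,
            "x_cm": x,
            "y_cm": y,
            "vx_mps": self.vel[:, 0],
            "vy_mps": self.vel[:, 1],
            "state": self.state,
            "lap": self.lap_index,
            "direction": self.direction,
        })

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------- fBm speeds

def fractional_gaussian_noise(
    n: int, hurst: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance fractional Gaussian noise via circulant embedding.

    Davies-Harte method: embed the fGn autocovariance in a circulant matrix
    whose eigenvalues are obtained by FFT.  Falls back to Hosking recursion
    if the embedding is not nonnegative (rare for H in (0, 1)).
    """
    if n < 1:
        return np.zeros(0)
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n)
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2n
    eig = np.fft.rfft(row).real
    if (eig < -1e-8).any():
        return _hosking_fgn(n, hurst, rng)
    eig = np.clip(eig, 0.0, None)
    m = len(row)
    # Hermitian-symmetric complex Gaussian spectrum
    z = rng.standard_normal(len(eig)) + 1j * rng.standard_normal(len(eig))
    z[0] = z[0].real * np.sqrt(2)
    if m % 2 == 0:
        z[-1] = z[-1].real * np.sqrt(2)
    spectrum = z * np.sqrt(eig * m / 2.0)
    sample = np.fft.irfft(spectrum, n=m) / np.sqrt(m)
    return sample[:n] * np.sqrt(m)


def _hosking_fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    k = np.arange(n, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    out = np.empty(n)
    phi = np.zeros(n)
    prev = np.zeros(n)
    v = 1.0
    out[0] = rng.standard_normal()
    for i in range(1, n):
        phi[i - 1] = gamma[i]
        for j in range(i - 1):
            phi[j] = prev[j]
            phi[i - 1] -= prev[j] * gamma[i - 1 - j]
        phi[i - 1] /= v
        for j in range(i - 1):
            phi[j] = prev[j] - phi[i - 1] * prev[i - 2 - j]
        v *= 1 - phi[i - 1] ** 2
        out[i] = np.sqrt(v) * rng.standard_normal() + phi[:i][::-1] @ out[:i]
        prev[:i] = phi[:i]
    return out


def _fbm_speed_profile(
    n_steps: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Speed (m/s) fluctuating around the target via a standardized fBm path."""
    noise = fractional_gaussian_noise(n_steps, config.fbm_hurst, rng)
    path = np.cumsum(noise)
    sd = path.std()
    z = (path - path.mean()) / sd if sd > 0 else np.zeros_like(path)
    speed = config.run_speed_target * (1.0 + config.fbm_rel_amp * z)
    return np.clip(speed, config.min_speed, None)


# --------------------------------------------------------------- 1D track

def generate_track_trajectory(
    config: SimulationConfig,
    n_laps: int,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> Trajectory:
    """Alternating end-to-end runs separated by idle periods.

    Layout per lap: idle (at the current end), brief allocentric pulse, then
    a run to the opposite end; a final idle period closes the session.  The
    first lap runs rightward from 0 cm.
    """
    if n_laps < 1:
        raise ValueError("n_laps must be >= 1")
    rng = _as_generator(seed)
    dt_s = config.dt / 1000.0
    L = config.track_length_cm
    idle_steps = int(round(config.idle_duration_s * 1000.0 / config.dt))
    allo_steps = int(round(config.allo_duration_s * 1000.0 / config.dt))
    theta = np.deg2rad(config.track_angle_deg)
    track_dir = np.array([np.cos(theta), np.sin(theta)])

    pos_parts, vel_parts, state_parts, lap_parts, dir_parts = [], [], [], [], []
    psi0 = rng.uniform(0.0, 2.0 * np.pi, size=n_laps)

    def emit(n, pos_cm, vel2, state, lap, direction):
        pos_parts.append(pos_cm)
        vel_parts.append(vel2)
        state_parts.append(np.full(n, int(state), dtype=np.uint8))
        lap_parts.append(np.full(n, lap, dtype=np.int32))
        dir_parts.append(np.full(n, direction, dtype=np.int8))

    current = 0.0
    for lap in range(n_laps):
        direction = 1 if lap % 2 == 0 else -1
        emit(idle_steps, np.full(idle_steps, current),
             np.zeros((idle_steps, 2)), BehavioralState.IDLE, -1, 0)
        emit(allo_steps, np.full(allo_steps, current),
             np.zeros((allo_steps, 2)), BehavioralState.ALLOCENTRIC, -1, 0)
        # run segment: integrate fBm speed until the opposite end is reached
        est = int(np.ceil((L / 100.0) / (config.run_speed_target * dt_s)))
        speed = _fbm_speed_profile(4 * est + 16, config, rng)
        step_cm = speed * dt_s * 100.0
        travelled = np.cumsum(step_cm)
        n_run = int(np.searchsorted(travelled, L)) + 1
        n_run = min(n_run, len(speed))
        d = travelled[:n_run].copy()
        d[-1] = min(d[-1], L)
        pos_run = current + direction * d
        v_run = np.outer(direction * speed[:n_run], track_dir)
        emit(n_run, pos_run, v_run, BehavioralState.RUN, lap, direction)
        current = current + direction * d[-1]
        current = min(max(current, 0.0), L)
    emit(idle_steps, np.full(idle_steps, current),
         np.zeros((idle_steps, 2)), BehavioralState.IDLE, -1, 0)

    return Trajectory(
        dt=config.dt,
        pos=np.concatenate(pos_parts),
        vel=np.concatenate(vel_parts),
        state=np.concatenate(state_parts),
        lap_index=np.concatenate(lap_parts),
        direction=np.concatenate(dir_parts),
        track_length_cm=L,
        is_1d=True,
        psi0=psi0,
    )


# --------------------------------------------------------------- open field

def generate_open_field_trajectory(
    config: SimulationConfig,
    duration_s: float,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> Trajectory:
    """Smooth random-walk path in a square arena with reflective walls.

    Velocity follows an Ornstein-Uhlenbeck process whose stationary speed
    distribution has mean equal to the target run speed.
    """
    rng = _as_generator(seed)
    n_steps = int(round(duration_s * 1000.0 / config.dt))
    dt_s = config.dt / 1000.0
    side = config.arena_side_cm
    tau_v = 1.0  # s, velocity relaxation time
    sigma = config.run_speed_target / np.sqrt(np.pi / 2.0)  # Rayleigh mean -> target
    pos = np.empty((n_steps, 2))
    vel = np.empty((n_steps, 2))
    p = np.array([side / 2.0, side / 2.0])
    v = rng.standard_normal(2) * sigma
    a = np.exp(-dt_s / tau_v)
    b = sigma * np.sqrt(1.0 - a ** 2)
    for i in range(n_steps):
        v = a * v + b * rng.standard_normal(2)
        p = p + v * dt_s * 100.0
        for ax in range(2):  # reflective walls
            if p[ax] < 0:
                p[ax] = -p[ax]
                v[ax] = -v[ax]
            elif p[ax] > side:
                p[ax] = 2 * side - p[ax]
                v[ax] = -v[ax]
        pos[i] = p
        vel[i] = v
    state = np.full(n_steps, int(BehavioralState.RUN), dtype=np.uint8)
    return Trajectory(
        dt=config.dt, pos=pos, vel=vel, state=state,
        lap_index=np.zeros(n_steps, dtype=np.int32),
        direction=np.zeros(n_steps, dtype=np.int8),
        track_length_cm=side, is_1d=False,
        psi0=rng.uniform(0.0, 2.0 * np.pi, size=1),
    )


# --------------------------------------------------------------- velocity

def velocity_drive_factor(
    vel: np.ndarray, population: str, alpha_gain: float = 0.25
) -> np.ndarray | float:
    """Drive multiplier 1 + alpha (E_P . V) for one excitatory population."""
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}")
    e = np.asarray(SPATIAL_DIRECTIONS[population])
    v = np.asarray(vel, dtype=float)
    val = 1.0 + alpha_gain * (v @ e)
    return float(val) if np.ndim(val) == 0 else val


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
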