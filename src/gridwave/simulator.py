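"""Leaky integrate-and-fire network core.

Five overlapping populations (four excitatory: N, S, W, E; one inhibitory)
live on an n x n sheet.  Membrane potentials follow explicit-Euler leaky
integrator dynamics; a neuron whose potential reaches the threshold of 1
spikes and is reset to 0, and potentials are floored at -1 as a limit on
hyperpolarization.  Spikes reach their targets after population-specific
synaptic delays (exc->exc 5 ms, exc->inh 2 ms, inh->exc 2 ms) through
translation-invariant kernels applied by FFT convolution (zero-padded for
the nonperiodic sheet, circular for periodic boundaries).

Because every target population receives the same summed excitatory field
(only the delay differs), each step performs exactly two convolutions: the
directionally shifted, population-summed excitatory spike field with the
radial excitatory kernel, and the inhibitory spike field with the surround
kernel.  Convolution results are queued in ring buffers and read back at the
appropriate delays, which conserves every spike exactly once per pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.fft

from .config import BehavioralState, SimulationConfig, resolve_params
from .kernels import (
    POPULATIONS,
    SHEET_DIRECTIONS,
    SPATIAL_DIRECTIONS,
    build_kernels,
    excitatory_drive_field,
    excitatory_kernel,
    inhibitory_kernel,
    learn_allocentric_drive,
)
from .trajectory import Trajectory, generate_track_trajectory

__all__ = [
    "Network",
    "SpikeRecord",
    "path_integration_displacement",
    "run_session",
    "setup_phase",
]

N_EXC = 4
INH = 4  # index of the inhibitory population


@dataclass
class SpikeRecord:
    """Spike events from recorded neurons plus session traces.

    ``events`` columns: population index (0..3 for N,S,W,E), sheet y, sheet
    x, and the timestep index.  ``drive_trace`` holds the scalar inhibitory
    drive per step (used downstream for theta-phase labeling); ``snapshots``
    are optional per-interval spike-count fields of one population.
    """

    dt: float
    pop: np.ndarray            # uint8
    y: np.ndarray              # uint16
    x: np.ndarray              # uint16
    step: np.ndarray           # int64
    drive_trace: np.ndarray    # float32, per step
    snapshots: np.ndarray | None = None      # (n_snap, h, w) uint16
    snapshot_steps: np.ndarray | None = None
    snapshot_origin: tuple[int, int] = (0, 0)
    trajectory: Trajectory | None = None
    config: SimulationConfig | None = None

    @property
    def t_ms(self) -> np.ndarray:
        return self.step * self.dt

    @property
    def n_events(self) -> int:
        return len(self.step)


class _Conv2D:
    """FFT convolution with a fixed centered kernel ('same' output)."""

    def __init__(self, n: int, kernel: np.ndarray, periodic: bool):
        self.n = n
        self.periodic = periodic
        self.half = kernel.shape[0] // 2
        if periodic:
            kh = self.half
            wrapped = np.zeros((n, n), dtype=np.float32)
            src = kernel.astype(np.float32)
            for i in range(kernel.shape[0]):
                for j in range(kernel.shape[1]):
                    wrapped[(i - kh) % n, (j - kh) % n] += src[i, j]
            self.size = n
            self.kf = scipy.fft.rfft2(wrapped)
            self._crop = None
        else:
            self.size = scipy.fft.next_fast_len(n + kernel.shape[0] - 1)
            pad = np.zeros((self.size, self.size), dtype=np.float32)
            pad[: kernel.shape[0], : kernel.shape[1]] = kernel
            self.kf = scipy.fft.rfft2(pad)
            self._crop = (self.half, self.half + n)

    def __call__(self, field: np.ndarray) -> np.ndarray:
        if self.periodic:
            out = scipy.fft.irfft2(scipy.fft.rfft2(field) * self.kf, s=(self.n, self.n))
            return out.astype(np.float32, copy=False)
        pad = np.zeros((self.size, self.size), dtype=np.float32)
        pad[: self.n, : self.n] = field
        full = scipy.fft.irfft2(scipy.fft.rfft2(pad) * self.kf, s=(self.size, self.size))
        a, b = self._crop
        return full[a:b, a:b].astype(np.float32, copy=False)


class Network:
    """Stateful LIF network advancing one behavioral schedule step at a time.

    All randomness derives from the seed: initial membrane potentials come
    from a dedicated stream, and per-step noise uses a counter-based Philox
    stream keyed on (seed-derived key, step), so identical (config, seed)
    pairs reproduce sessions exactly and runs are restartable.
    """

    def __init__(self, config: SimulationConfig, seed: int | np.random.SeedSequence = 0):
        self.config = config
        n = config.n
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        ss_init, ss_noise = ss.spawn(2)
        self._noise_key = int(ss_noise.generate_state(1, np.uint64)[0])
        init_rng = np.random.default_rng(ss_init)
        pool_size = max(1 << self._POOL_BITS, 8 * 5 * n * n)
        self._pool = np.random.default_rng(ss_noise).standard_normal(
            pool_size, dtype=np.float32
        )

        self.kernels = build_kernels(config)
        periodic = config.boundary == "periodic"
        self.periodic = periodic
        # single radial excitatory kernel; directional shifts applied to the
        # spike fields (integer xi) before the shared convolution
        exc_half = int(np.ceil(config.r_w_exc))
        ax = np.arange(-exc_half, exc_half + 1)
        r = np.sqrt(ax[:, None] ** 2 + ax[None, :] ** 2)
        w_exc = np.asarray(excitatory_kernel(r, config.w_mag_exc, config.r_w_exc), dtype=np.float32)
        self._conv_exc = _Conv2D(n, w_exc, periodic)
        self._conv_inh = _Conv2D(n, self.kernels.w_inh_out.astype(np.float32), periodic)

        self.xi = int(round(config.xi_shift))
        if abs(config.xi_shift - self.xi) > 1e-9:
            raise ValueError("xi_shift must be an integer number of neurons")

        self.d_ee = self._delay_steps(config.tau_s_ee)
        self.d_ei = self._delay_steps(config.tau_s_ei)
        self.d_ii = self._delay_steps(config.tau_s_inh)
        self._exc_buf = np.zeros((self.d_ee, n, n), dtype=np.float32)
        self._inh_buf = np.zeros((self.d_ii, n, n), dtype=np.float32)

        self.phi = init_rng.random((5, n, n)).astype(np.float32)
        self.spikes = np.zeros((5, n, n), dtype=bool)
        self.k = 0  # global step counter

        self._sigma_exc = np.float32(np.sqrt(config.noise_var_exc))
        self._sigma_inh = np.float32(np.sqrt(config.noise_var_inh))
        self._ce = np.float32(config.dt / config.tau_m_exc)
        self._ci = np.float32(config.dt / config.tau_m_inh)
        self._spatial_dirs = np.array([SPATIAL_DIRECTIONS[p] for p in POPULATIONS])
        self._sheet_dirs = [SHEET_DIRECTIONS[p] for p in POPULATIONS]

        # state-dependent excitatory drive maps (allocentric maps set later)
        self.drive_maps = {
            BehavioralState.RUN: excitatory_drive_field(config, "run").astype(np.float32),
            BehavioralState.IDLE: excitatory_drive_field(config, "idle").astype(np.float32),
            # fallback during allocentric segments before/without learned maps
            BehavioralState.ALLOCENTRIC: excitatory_drive_field(config, "allo").astype(np.float32),
        }
        self.allo_maps: dict[int, np.ndarray] = {}

    def _delay_steps(self, tau_ms: float) -> int:
        d = int(round(tau_ms / self.config.dt))
        if d < 1:
            raise ValueError("synaptic delays must be at least one timestep")
        return d

    # ------------------------------------------------------------ noise
    _POOL_BITS = 24

    def _noise(self, k: int) -> np.ndarray:
        """Per-step i.i.d. normal noise field, scaled per population.

        Deviates are drawn from a large pre-generated pool at a
        counter-based offset (Knuth multiplicative hash of the step index),
        which keeps sessions reproducible and restartable while avoiding
        per-step generator costs.  With the default noise s.d. of 0.002 the
        pool recurrence (> 60 steps apart) has no measurable effect.
        """
        need = 5 * self.config.n * self.config.n
        span = self._pool.size - need
        off = int((k * 2654435761 + self._noise_key) % span)
        z = self._pool[off : off + need].reshape(self.phi.shape).copy()
        z[:N_EXC] *= self._sigma_exc
        z[INH] *= self._sigma_inh
        return z

    # ------------------------------------------------------------ stepping
    def step(
        self,
        vel: np.ndarray,
        state: BehavioralState | int,
        a_inh_value: float,
        a_exc_map: np.ndarray | None = None,
    ) -> np.ndarray:
        """Advance one timestep; returns the (5, n, n) boolean spike field."""
        k = self.k
        exc_in = self._exc_buf[(k - self.d_ee) % self.d_ee] if k >= self.d_ee else 0.0
        exc_to_inh = self._exc_buf[(k - self.d_ei) % self.d_ee] if k >= self.d_ei else 0.0
        inh_in = self._inh_buf[(k - self.d_ii) % self.d_ii] if k >= self.d_ii else 0.0

        if a_exc_map is None:
            a_exc_map = self.drive_maps[BehavioralState(int(state))]
        zeta = self._noise(k)

        vfac = 1.0 + self.config.alpha_gain * (self._spatial_dirs @ np.asarray(vel, dtype=float))
        phi = self.phi
        if self.config.synapse_mode == "instantaneous":
            # delta synapses: delayed weighted spikes jump the potential
            # directly; drive and noise pass through the leaky integrator
            shared = np.asarray(exc_in + inh_in, dtype=np.float32)
            for p in range(N_EXC):
                rhs = np.float32(vfac[p]) * a_exc_map + zeta[p]
                rhs -= phi[p]
                phi[p] += self._ce * rhs
                phi[p] += shared
            phi[INH] += self._ci * (
                np.float32(a_inh_value) + zeta[INH] - phi[INH]
            )
            phi[INH] += exc_to_inh
        else:
            shared = exc_in + inh_in  # same recurrent input for every excitatory population
            for p in range(N_EXC):
                rhs = shared + np.float32(vfac[p]) * a_exc_map
                rhs += zeta[p]
                rhs -= phi[p]
                phi[p] += self._ce * rhs
            rhs_i = exc_to_inh + np.float32(a_inh_value) + zeta[INH]
            phi[INH] += self._ci * (rhs_i - phi[INH])

        if k % 128 == 0 and not np.isfinite(phi).all():
            raise FloatingPointError(
                f"non-finite membrane potential at step {k}; simulation aborted"
            )

        spikes = phi >= 1.0
        phi[spikes] = 0.0
        np.maximum(phi, -1.0, out=phi)
        self.spikes = spikes

        # queue this step's spikes for delayed delivery
        field = self._shifted_exc_field(spikes)
        self._exc_buf[k % self.d_ee] = self._conv_exc(field) if field.any() else 0.0
        s_inh = spikes[INH]
        self._inh_buf[k % self.d_ii] = (
            self._conv_inh(s_inh.astype(np.float32)) if s_inh.any() else 0.0
        )
        self.k += 1
        return spikes

    def _shifted_exc_field(self, spikes: np.ndarray) -> np.ndarray:
        """Sum of excitatory spike fields, each displaced by xi along its direction."""
        n = self.config.n
        out = np.zeros((n, n), dtype=np.float32)
        xi = self.xi
        for p, (dy, dx) in enumerate(self._sheet_dirs):
            s = spikes[p]
            oy, ox = dy * xi, dx * xi
            if self.periodic:
                out += np.roll(np.roll(s, oy, axis=0), ox, axis=1)
            else:
                ys0, ys1 = max(0, oy), n + min(0, oy)
                xs0, xs1 = max(0, ox), n + min(0, ox)
                out[ys0:ys1, xs0:xs1] += s[ys0 - oy : ys1 - oy, xs0 - ox : xs1 - ox]
        return out


# ---------------------------------------------------------------- sessions

def _resolve_inh_drive(config: SimulationConfig, trajectory: Trajectory) -> np.ndarray:
    """Per-step scalar inhibitory drive a_inh(t) with per-lap theta offsets."""
    t_s = trajectory.t_ms / 1000.0
    out = np.empty(trajectory.n_steps, dtype=np.float32)
    for st in BehavioralState:
        p = resolve_params(config, st)
        mask = trajectory.state == int(st)
        if not mask.any():
            continue
        if p.a_theta_inh == 0:
            out[mask] = p.a_mag_inh
        else:
            lap = trajectory.lap_index
            psi = np.zeros(trajectory.n_steps)
            valid = lap >= 0
            psi[valid] = trajectory.psi0[lap[valid]]
            out[mask] = (
                p.a_mag_inh
                - p.a_theta_inh * np.cos(2 * np.pi * p.f_theta * t_s[mask] + psi[mask])
            )
    return out


@dataclass
class _Recorder:
    pop: list = field(default_factory=list)
    y: list = field(default_factory=list)
    x: list = field(default_factory=list)
    step: list = field(default_factory=list)

    def collect(self, k, spikes, idx):
        if idx is None:
            hits = np.nonzero(spikes[:N_EXC])
            if hits[0].size:
                self.pop.append(hits[0].astype(np.uint8))
                self.y.append(hits[1].astype(np.uint16))
                self.x.append(hits[2].astype(np.uint16))
                self.step.append(np.full(hits[0].size, k, dtype=np.int64))
            return
        pi, yi, xi = idx
        vals = spikes[pi, yi, xi]
        if vals.any():
            w = np.nonzero(vals)[0]
            self.pop.append(pi[w].astype(np.uint8))
            self.y.append(yi[w].astype(np.uint16))
            self.x.append(xi[w].astype(np.uint16))
            self.step.append(np.full(w.size, k, dtype=np.int64))

    def finish(self) -> tuple[np.ndarray, ...]:
        if not self.step:
            z = np.zeros(0)
            return z.astype(np.uint8), z.astype(np.uint16), z.astype(np.uint16), z.astype(np.int64)
        return (
            np.concatenate(self.pop),
            np.concatenate(self.y),
            np.concatenate(self.x),
            np.concatenate(self.step),
        )


def run_session(
    config: SimulationConfig,
    trajectory: Trajectory,
    seed: int | np.random.SeedSequence = 0,
    allo_maps: dict[int, np.ndarray] | None = None,
    record_index: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    snapshot_pop: int | None = None,
    snapshot_crop: tuple[slice, slice] | None = None,
    network: Network | None = None,
    settle: bool = True,
    tally_mask: np.ndarray | None = None,
    progress: Callable[[int, int], None] | None = None,
) -> SpikeRecord:
    """Simulate a full behavioral session and return its spike record.

    ``record_index`` restricts stored spike events to selected excitatory
    neurons (population, y, x index arrays); by default all excitatory
    spikes are stored, which is only advisable for short simulations.
    ``allo_maps`` maps a track-end key (0 or 1) to a learned drive field
    used during allocentric-correction segments.  ``tally_mask`` (boolean
    per step) accumulates summed excitatory spike counts for map learning.
    """
    if not trajectory.is_1d and config.allocentric_enabled and allo_maps:
        raise ValueError("allocentric maps apply to 1D track sessions")
    net = network or Network(config, seed)
    if net.config.n != config.n:
        raise ValueError("network/config sheet size mismatch")
    n = config.n
    a_inh = _resolve_inh_drive(config, trajectory)
    rec = _Recorder()
    tally = np.zeros((n, n), dtype=np.int64) if tally_mask is not None else None

    snap_every = max(1, int(round(config.snapshot_interval_ms / config.dt)))
    snaps, snap_steps = [], []
    if snapshot_pop is not None:
        crop = snapshot_crop or (slice(0, n), slice(0, n))
        acc = np.zeros((crop[0].stop - crop[0].start, crop[1].stop - crop[1].start), dtype=np.uint16)

    if settle:
        # relax from random initial potentials under the first state's drive
        st0 = BehavioralState(int(trajectory.state[0]))
        p0 = resolve_params(config, st0)
        n_settle = int(round(config.settle_duration_s * 1000.0 / config.dt))
        for _ in range(n_settle):
            net.step(np.zeros(2), st0, p0.a_mag_inh)

    allo_maps = allo_maps or {}
    L = trajectory.track_length_cm
    pos = np.atleast_2d(trajectory.pos.T).T[:, 0] if trajectory.is_1d else None

    for k in range(trajectory.n_steps):
        st = int(trajectory.state[k])
        a_map = None
        if st == int(BehavioralState.ALLOCENTRIC) and allo_maps:
            end = 0 if (pos is not None and pos[k] < L / 2) else 1
            a_map = allo_maps.get(end)
        spikes = net.step(trajectory.vel[k], st, float(a_inh[k]), a_exc_map=a_map)
        rec.collect(k, spikes, record_index)
        if tally is not None and tally_mask[k]:
            tally += spikes[:N_EXC].sum(axis=0)
        if snapshot_pop is not None:
            acc += spikes[snapshot_pop][crop]
            if (k + 1) % snap_every == 0:
                snaps.append(acc.copy())
                snap_steps.append(k + 1 - snap_every // 2)
                acc[:] = 0
        if progress is not None and k % 5000 == 0:
            progress(k, trajectory.n_steps)

    pop, y, x, step = rec.finish()
    record = SpikeRecord(
        dt=config.dt, pop=pop, y=y, x=x, step=step,
        drive_trace=a_inh,
        snapshots=np.array(snaps, dtype=np.uint16) if snaps else None,
        snapshot_steps=np.array(snap_steps) if snaps else None,
        snapshot_origin=(
            (snapshot_crop[0].start, snapshot_crop[1].start) if snapshot_crop else (0, 0)
        ),
        trajectory=trajectory,
        config=config,
    )
    record.tally = tally  # type: ignore[attr-defined]
    return record


def setup_phase(
    config: SimulationConfig, seed: int | np.random.SeedSequence = 0
) -> dict[int, np.ndarray]:
    """Learn the allocentric drive maps for both track ends.

    One run in each direction, each followed by a stationary learning period
    at the track end just reached; summed excitatory spike tallies during
    each learning period are linearly rescaled into a drive map.
    """
    if not config.allocentric_enabled:
        return {}
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_net, ss_traj = ss.spawn(2)
    net = Network(config, ss_net)
    learn_cfg = config.replace(
        idle_duration_s=config.learning_duration_s, allo_duration_s=config.dt / 1000.0
    )
    traj = generate_track_trajectory(learn_cfg, n_laps=2, seed=np.random.default_rng(ss_traj))
    # learning periods: the idle spans that follow each completed run
    state = traj.state
    idle = state == int(BehavioralState.IDLE)
    lap_done = np.zeros(traj.n_steps, dtype=bool)
    seen_run = False
    for k in range(traj.n_steps):
        if state[k] == int(BehavioralState.RUN):
            seen_run = True
        lap_done[k] = seen_run
    tally_mask = idle & lap_done
    # idle periods here use run-state drive so that bumps persist while learning
    learn_traj = Trajectory(
        dt=traj.dt, pos=traj.pos, vel=traj.vel,
        state=np.where(idle, int(BehavioralState.RUN), traj.state).astype(np.uint8),
        lap_index=traj.lap_index, direction=traj.direction,
        track_length_cm=traj.track_length_cm, is_1d=True, psi0=traj.psi0,
    )
    pos = np.atleast_2d(traj.pos.T).T[:, 0]
    L = traj.track_length_cm

    maps: dict[int, np.ndarray] = {}
    a_inh = _resolve_inh_drive(config, learn_traj)
    n_settle = int(round(config.settle_duration_s * 1000.0 / config.dt))
    p0 = resolve_params(config, "run")
    for _ in range(n_settle):
        net.step(np.zeros(2), BehavioralState.RUN, p0.a_mag_inh)
    per_end = {0: np.zeros((config.n, config.n), dtype=np.int64),
               1: np.zeros((config.n, config.n), dtype=np.int64)}
    for k in range(learn_traj.n_steps):
        spikes = net.step(learn_traj.vel[k], int(learn_traj.state[k]), float(a_inh[k]))
        if tally_mask[k]:
            end = 1 if pos[k] > L / 2 else 0
            per_end[end] += spikes[:N_EXC].sum(axis=0)
    for end in (0, 1):
        if per_end[end].max() <= 0:
            raise RuntimeError("allocentric setup failed: no bumps formed during learning")
        maps[end] = learn_allocentric_drive(per_end[end], config).astype(np.float32)
    return maps


def path_integration_displacement(
    config: SimulationConfig,
    fixed_vel: np.ndarray | tuple[float, float],
    duration_s: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    fixed_a_inh: float | None = None,
    settle_s: float | None = None,
    theta: bool = False,
) -> tuple[float, float]:
    """Bump-lattice displacement (dy, dx in neurons) under constant velocity.

    Runs the network in the run state with constant velocity, tracking the
    lattice phase through spatial cross-correlation of successive central
    activity snapshots.  The inhibitory drive is held fixed by default;
    ``theta=True`` applies the run-state theta oscillation instead (the
    condition under which the animal actually path-integrates).
    """
    from .bumps import track_lattice_displacement

    net = Network(config, seed)
    p = resolve_params(config, "run")
    a_mag = p.a_mag_inh if fixed_a_inh is None else fixed_a_inh
    vel = np.asarray(fixed_vel, dtype=float)
    n = config.n
    n_settle = int(round((config.settle_duration_s if settle_s is None else settle_s) * 1000 / config.dt))
    for _ in range(n_settle):
        net.step(np.zeros(2), BehavioralState.RUN, a_mag)
    n_steps = int(round(duration_s * 1000.0 / config.dt))
    every = max(1, int(round(config.snapshot_interval_ms / config.dt)))
    half = n // 4
    crop = (slice(n // 2 - half, n // 2 + half), slice(n // 2 - half, n // 2 + half))
    acc = np.zeros((2 * half, 2 * half), dtype=np.float32)
    snaps = []
    for k in range(n_steps):
        a_inh = a_mag
        if theta:
            a_inh = a_mag - p.a_theta_inh * np.cos(
                2.0 * np.pi * p.f_theta * k * config.dt / 1000.0
            )
        spikes = net.step(vel, BehavioralState.RUN, float(a_inh))
        acc += spikes[:N_EXC].sum(axis=0)[crop]
        if (k + 1) % every == 0:
            snaps.append(acc.copy())
            acc[:] = 0
    dy, dx = track_lattice_displacement(np.array(snaps))
    return float(dy), float(dx)
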