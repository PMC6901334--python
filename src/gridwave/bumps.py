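"""Attractor-bump characterization and simplified phase-precession models.

Bump size and speed are measured in dedicated simulations with fixed
(non-oscillating) inhibitory drive and constant animal velocity: bumps are
segmented from smoothed spike-count snapshots as supra-threshold connected
components, and lattice speed is tracked by spatial cross-correlation of
successive snapshots.  Both quantities vary linearly with the inhibitory
drive over the theta range — size decreasing, speed increasing — which is
the mechanistic core of phase precession and theta sequences.

Two simplified models build on those measurements: a deterministic
threshold model (a neuron fires whenever it sits inside an oscillating-size
bump, subject to a refractory period) and a stochastic rate model (spiking
is an inhomogeneous point process with rate proportional to the average
bump activity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .config import BehavioralState, SimulationConfig, resolve_params

__all__ = [
    "AverageBump",
    "BumpMetrics",
    "average_bump_shape",
    "default_drive_levels",
    "fixed_drive_sweep",
    "segment_bumps",
    "simulate_poisson_pass",
    "simulate_threshold_pass",
    "track_lattice_displacement",
]

N_EXC = 4


def default_drive_levels(config: SimulationConfig) -> np.ndarray:
    """Five fixed inhibitory-drive levels spanning the theta oscillation.

    Endpoints are a_mag +/- a_theta of the run state (0.52..0.92 with the
    standard parameters).
    """
    p = resolve_params(config, "run")
    return np.linspace(p.a_mag_inh - p.a_theta_inh, p.a_mag_inh + p.a_theta_inh, 5)


# -------------------------------------------------------------- segmentation

def segment_bumps(
    snapshot: np.ndarray,
    smooth_sigma: float = 1.5,
    threshold_frac: float = 0.3,
    min_area: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Bump centroids and equivalent-circle diameters from one snapshot.

    The snapshot (spike counts in a short window) is Gaussian-smoothed;
    connected components above ``threshold_frac`` of the smoothed maximum
    become bumps.  Returns (centers (K, 2) as (y, x), diameters (K,)).
    """
    img = ndimage.gaussian_filter(np.asarray(snapshot, dtype=float), smooth_sigma)
    peak = img.max()
    if peak <= 0:
        return np.zeros((0, 2)), np.zeros(0)
    lab, nlab = ndimage.label(img >= threshold_frac * peak)
    centers, diams = [], []
    for j in range(1, nlab + 1):
        area = int((lab == j).sum())
        if area < min_area:
            continue
        cy, cx = ndimage.center_of_mass(img, lab, j)
        centers.append((cy, cx))
        diams.append(2.0 * np.sqrt(area / np.pi))
    return np.asarray(centers, dtype=float).reshape(-1, 2), np.asarray(diams)


def _pair_shift(prev: np.ndarray, cur: np.ndarray, max_step: int) -> np.ndarray | None:
    """Sub-pixel (dy, dx) by which ``cur`` is displaced relative to ``prev``."""
    h, w = prev.shape
    if not np.any(prev) or not np.any(cur):
        return None
    # circular cross-correlation via FFT; fine for shifts << field size
    f = np.fft.rfft2(cur) * np.conj(np.fft.rfft2(prev))
    cc = np.fft.fftshift(np.fft.irfft2(f, s=(h, w)))
    cy, cx = h // 2, w // 2
    win = cc[cy - max_step : cy + max_step + 1, cx - max_step : cx + max_step + 1]
    iy, ix = np.unravel_index(np.argmax(win), win.shape)

    def refine(v, i):
        if 0 < i < len(v) - 1:
            denom = v[i - 1] - 2 * v[i] + v[i + 1]
            if denom != 0:
                return float(np.clip(0.5 * (v[i - 1] - v[i + 1]) / denom, -0.5, 0.5))
        return 0.0

    dy = iy - max_step + refine(win[:, ix], iy)
    dx = ix - max_step + refine(win[iy, :], ix)
    return np.array([dy, dx])


def lattice_displacement_trace(
    snapshots: np.ndarray,
    smooth_sigma: float = 1.5,
    block: int = 5,
    max_step: int | None = None,
) -> np.ndarray:
    """Cumulative (dy, dx) lattice displacement per snapshot block.

    Snapshots are summed into blocks of ``block`` frames to suppress spiking
    noise, then consecutive blocks are cross-correlated; the correlation
    peak nearest zero lag (within ``max_step``) gives each inter-block
    shift, refined to sub-pixel precision by parabolic interpolation.
    Valid while the lattice moves less than half a lattice spacing per
    block.  Returns an (n_blocks, 2) cumulative trace starting at (0, 0).
    """
    snaps = np.asarray(snapshots, dtype=float)
    if snaps.ndim != 3 or len(snaps) < 2 * block:
        return np.zeros((1, 2))
    n_blocks = len(snaps) // block
    blocks = snaps[: n_blocks * block].reshape(n_blocks, block, *snaps.shape[1:]).sum(axis=1)
    h, w = blocks.shape[1:]
    if max_step is None:
        max_step = min(h, w) // 8
    trace = np.zeros((n_blocks, 2))
    prev = ndimage.gaussian_filter(blocks[0], smooth_sigma)
    prev -= prev.mean()
    for i, b in enumerate(blocks[1:], start=1):
        cur = ndimage.gaussian_filter(b, smooth_sigma)
        cur -= cur.mean()
        shift = _pair_shift(prev, cur, max_step)
        trace[i] = trace[i - 1] + (shift if shift is not None else 0.0)
        prev = cur
    return trace


def track_lattice_displacement(
    snapshots: np.ndarray,
    smooth_sigma: float = 1.5,
    block: int = 5,
) -> tuple[float, float]:
    """Total (dy, dx) lattice displacement across a snapshot sequence.

    A robust linear fit to the cumulative displacement trace (see
    :func:`lattice_displacement_trace`) extrapolated over the full duration,
    which suppresses endpoint noise of the chained estimates.
    """
    trace = lattice_displacement_trace(snapshots, smooth_sigma, block)
    n = len(trace)
    if n < 3:
        return float(trace[-1, 0]), float(trace[-1, 1])
    t = np.arange(n, dtype=float)
    span = len(np.asarray(snapshots)) / block  # duration in block units
    vy = np.polyfit(t, trace[:, 0], 1)[0]
    vx = np.polyfit(t, trace[:, 1], 1)[0]
    return float(vy * span), float(vx * span)


# -------------------------------------------------------------- drive sweep

@dataclass
class BumpMetrics:
    """Bump diameter and speed per fixed inhibitory-drive level, with fits."""

    drive_levels: np.ndarray
    diameter: np.ndarray          # neurons, mean over snapshots
    diameter_sd: np.ndarray
    speed: np.ndarray             # neurons/s, lattice speed
    diameter_fit: dict            # slope, intercept, r2, p
    speed_fit: dict

    def monotonic(self) -> tuple[bool, bool]:
        """(diameter decreasing, speed increasing) across the sweep."""
        return (
            bool(np.all(np.diff(self.diameter) < 0)),
            bool(np.all(np.diff(self.speed) > 0)),
        )


def _linfit(x: np.ndarray, y: np.ndarray) -> dict:
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue ** 2),
        "p": float(res.pvalue),
    }


def fixed_drive_sweep(
    config: SimulationConfig,
    drive_levels: np.ndarray | None = None,
    fixed_vel: tuple[float, float] = (0.5, 0.0),
    duration_s: float = 2.0,
    seed: int | np.random.SeedSequence = 0,
    population: int = 1,
    settle_s: float | None = None,
) -> BumpMetrics:
    """Bump diameter and lattice speed at each fixed inhibitory-drive level.

    Each level runs an independent simulation in the run state with
    a_theta_inh = 0 (the drive held constant at the level) and constant
    velocity.  Diameters come from :func:`segment_bumps` on central-region
    snapshots; speed from :func:`track_lattice_displacement`.
    """
    from .simulator import Network  # deferred to avoid an import cycle

    if drive_levels is None:
        drive_levels = default_drive_levels(config)
    drive_levels = np.asarray(drive_levels, dtype=float)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(len(drive_levels))
    n = config.n
    half = max(n // 4, min(40, n // 2 - 1))
    crop = (slice(n // 2 - half, n // 2 + half), slice(n // 2 - half, n // 2 + half))
    every = max(1, int(round(config.snapshot_interval_ms / config.dt)))
    n_settle = int(round(
        (config.settle_duration_s if settle_s is None else settle_s) * 1000.0 / config.dt
    ))
    n_steps = int(round(duration_s * 1000.0 / config.dt))
    vel = np.asarray(fixed_vel, dtype=float)

    diam_mean, diam_sd, speeds = [], [], []
    kept_levels = []
    for level, s in zip(drive_levels, seeds):
        net = Network(config, s)
        for _ in range(n_settle):
            net.step(np.zeros(2), BehavioralState.RUN, float(level))
        acc = np.zeros((2 * half, 2 * half), dtype=np.float32)
        snaps = []
        for k in range(n_steps):
            spk = net.step(vel, BehavioralState.RUN, float(level))
            acc += spk[population][crop]
            if (k + 1) % every == 0:
                snaps.append(acc.copy())
                acc[:] = 0
        snaps = np.asarray(snaps)
        # diameters from 30 ms accumulations: single-interval snapshots are
        # too sparse (a few spikes per bump) for stable segmentation
        per_diam = max(1, int(round(30.0 / config.snapshot_interval_ms)))
        nd = len(snaps) // per_diam
        diam_frames = snaps[: nd * per_diam].reshape(nd, per_diam, *snaps.shape[1:]).sum(1)
        diams = []
        for snap in diam_frames:
            _, d = segment_bumps(snap)
            diams.extend(d.tolist())
        if not diams:
            continue  # lattice lost at this level
        kept_levels.append(level)
        diam_mean.append(float(np.median(diams)))
        diam_sd.append(float(np.std(diams)))
        dy, dx = track_lattice_displacement(snaps)
        speeds.append(float(np.hypot(dy, dx) / duration_s))

    kept = np.asarray(kept_levels)
    if len(kept) < 2:
        raise RuntimeError("fixed-drive sweep found fewer than two usable levels")
    return BumpMetrics(
        drive_levels=kept,
        diameter=np.asarray(diam_mean),
        diameter_sd=np.asarray(diam_sd),
        speed=np.asarray(speeds),
        diameter_fit=_linfit(kept, np.asarray(diam_mean)),
        speed_fit=_linfit(kept, np.asarray(speeds)),
    )


# ---------------------------------------------------------- average bump

@dataclass
class AverageBump:
    """Mean bump activity by theta phase, in a constant-velocity frame.

    ``activity[b]`` is the average 2D spike density around the reference
    bump position in phase bin b; ``axis_profile[b]`` its projection onto
    the motion axis; ``peak_trace`` the sub-pixel peak offset along the
    motion axis per phase bin.
    """

    phase_centers_deg: np.ndarray
    offsets: np.ndarray            # relative sheet coordinate axis (neurons)
    activity: np.ndarray           # (n_phase, H, W)
    axis_profile: np.ndarray       # (n_phase, W)
    peak_trace: np.ndarray         # (n_phase,)
    motion_axis: np.ndarray        # unit vector (dy, dx)


def average_bump_shape(
    config: SimulationConfig,
    duration_s: float = 4.0,
    fixed_vel: tuple[float, float] = (0.5, 0.0),
    n_phase_bins: int = 12,
    half_window: int = 16,
    seed: int | np.random.SeedSequence = 0,
    population: int = 1,
) -> AverageBump:
    """Phase-resolved average bump in its constant-velocity reference frame.

    Runs the network in the run state (theta drive on, psi0 = 0, constant
    velocity), tracks bump centroids across 10 ms snapshots, fits a
    constant-velocity reference trajectory to each bump track per theta
    quadruplet, and accumulates spike offsets relative to that reference,
    binned by theta phase.
    """
    from .simulator import Network

    p = resolve_params(config, "run")
    if p.a_theta_inh <= 0:
        raise ValueError("average bump shape requires oscillating inhibitory drive")
    net = Network(config, seed)
    n = config.n
    n_settle = int(round(config.settle_duration_s * 1000.0 / config.dt))
    for _ in range(n_settle):
        net.step(np.zeros(2), BehavioralState.RUN, p.a_mag_inh)

    every = max(1, int(round(config.snapshot_interval_ms / config.dt)))
    n_steps = int(round(duration_s * 1000.0 / config.dt))
    vel = np.asarray(fixed_vel, dtype=float)
    f = p.f_theta
    dt = config.dt
    half = max(n // 4, min(40, n // 2 - 1))
    crop = (slice(n // 2 - half, n // 2 + half), slice(n // 2 - half, n // 2 + half))

    acc = np.zeros((2 * half, 2 * half), dtype=np.float32)
    snaps, snap_t = [], []
    spike_y, spike_x, spike_t = [], [], []
    y0, x0 = crop[0].start, crop[1].start
    for k in range(n_steps):
        t_ms = k * dt
        a_inh = p.a_mag_inh - p.a_theta_inh * np.cos(2 * np.pi * f * t_ms / 1000.0)
        spk = net.step(vel, BehavioralState.RUN, float(a_inh))
        sub = spk[population][crop]
        acc += sub
        ys, xs = np.nonzero(sub)
        if ys.size:
            spike_y.append(ys)
            spike_x.append(xs)
            spike_t.append(np.full(ys.size, t_ms))
        if (k + 1) % every == 0:
            snaps.append(acc.copy())
            snap_t.append(t_ms - (every - 1) * dt / 2.0)
            acc[:] = 0
    snaps = np.asarray(snaps)
    snap_t = np.asarray(snap_t)
    sy = np.concatenate(spike_y) if spike_y else np.zeros(0, int)
    sx = np.concatenate(spike_x) if spike_x else np.zeros(0, int)
    st = np.concatenate(spike_t) if spike_t else np.zeros(0)

    # --- track bump identities across snapshots (nearest-centroid matching);
    # tracking frames accumulate 30 ms so segmentation is stable
    per_track = max(1, int(round(30.0 / (every * dt))))
    nt = len(snaps) // per_track
    track_frames = snaps[: nt * per_track].reshape(nt, per_track, *snaps.shape[1:]).sum(1)
    track_t = snap_t[: nt * per_track].reshape(nt, per_track).mean(axis=1)
    tracks: dict[int, list[tuple[float, float, float]]] = {}
    prev_pos: dict[int, tuple[float, float]] = {}
    next_id = 0
    for snap, t_ms in zip(track_frames, track_t):
        centers, _ = segment_bumps(snap)
        new_prev: dict[int, tuple[float, float]] = {}
        for cy, cx in centers:
            best_id, best_d = None, 8.0  # bumps move << 8 neurons per 10 ms
            for tid, (py, px) in prev_pos.items():
                d = np.hypot(cy - py, cx - px)
                if d < best_d:
                    best_id, best_d = tid, d
            if best_id is None:
                best_id = next_id
                next_id += 1
            tracks.setdefault(best_id, []).append((t_ms, cy, cx))
            new_prev[best_id] = (cy, cx)
        prev_pos = new_prev

    cycle_ms = 1000.0 / f
    quad_ms = 4 * cycle_ms
    edge = 6.0
    H = W = 2 * half_window + 1
    n_phase = n_phase_bins
    act = np.zeros((n_phase, H, W))
    order = np.argsort(st)
    st_s, sy_s, sx_s = st[order], sy[order], sx[order]

    for tid, pts in tracks.items():
        pts = np.asarray(pts)
        if len(pts) < 4:
            continue
        t_lo, t_hi = pts[0, 0], pts[-1, 0]
        q0 = np.floor(t_lo / quad_ms) * quad_ms
        frame_ms = per_track * every * dt
        while q0 + quad_ms <= t_hi + frame_ms:
            w = (pts[:, 0] >= q0) & (pts[:, 0] < q0 + quad_ms)
            if w.sum() >= 0.7 * quad_ms / frame_ms:
                tt = pts[w, 0]
                cy_fit = np.polyfit(tt, pts[w, 1], 1)
                cx_fit = np.polyfit(tt, pts[w, 2], 1)
                # keep only bumps staying clear of the crop edge
                ys_ref = np.polyval(cy_fit, [q0, q0 + quad_ms])
                xs_ref = np.polyval(cx_fit, [q0, q0 + quad_ms])
                if (
                    min(ys_ref.min(), xs_ref.min()) > edge + half_window / 2
                    and max(ys_ref.max(), xs_ref.max()) < 2 * half - edge - half_window / 2
                ):
                    a = np.searchsorted(st_s, q0)
                    b = np.searchsorted(st_s, q0 + quad_ms)
                    for i in range(a, b):
                        ry = sy_s[i] - np.polyval(cy_fit, st_s[i])
                        rx = sx_s[i] - np.polyval(cx_fit, st_s[i])
                        iy = int(round(ry)) + half_window
                        ix = int(round(rx)) + half_window
                        if 0 <= iy < H and 0 <= ix < W:
                            phase = (st_s[i] / cycle_ms % 1.0) * 360.0
                            pb = min(int(phase / 360.0 * n_phase), n_phase - 1)
                            act[pb, iy, ix] += 1.0
            q0 += quad_ms

    axis = np.asarray(fixed_vel, dtype=float)
    nrm = np.linalg.norm(axis)
    motion = np.array([0.0, 1.0]) if nrm == 0 else np.array([axis[1], axis[0]]) / nrm
    # activity along the central axis: a slab of rows around the bump
    # center, so the profile retains the on/off modulation a neuron on the
    # bump's path actually experiences
    mid = half_window
    profile = act[:, max(0, mid - 2) : mid + 3, :].sum(axis=1)
    offsets = np.arange(-half_window, half_window + 1, dtype=float)
    peak = np.empty(n_phase)
    for b in range(n_phase):
        v = profile[b]
        if v.max() <= 0:
            peak[b] = np.nan
            continue
        i = int(np.argmax(v))
        d = 0.0
        if 0 < i < len(v) - 1:
            denom = v[i - 1] - 2 * v[i] + v[i + 1]
            if denom != 0:
                d = 0.5 * (v[i - 1] - v[i + 1]) / denom
        peak[b] = offsets[i] + d
    centers = (np.arange(n_phase) + 0.5) * 360.0 / n_phase
    return AverageBump(
        phase_centers_deg=centers, offsets=offsets, activity=act,
        axis_profile=profile, peak_trace=peak, motion_axis=motion,
    )


# ------------------------------------------------------- conceptual models

def simulate_threshold_pass(
    diameter_law: tuple[float, float],
    v_sheet: float,
    config: SimulationConfig | None = None,
    refractory_ms: float = 40.0,
    initial_phases_deg: np.ndarray | None = None,
    dt_ms: float = 1.0,
    margin: float = 1.5,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic threshold model of phase precession (one neuron, many laps).

    A bump of oscillating diameter D(t) = slope * a_inh(t) + intercept moves
    at constant sheet speed ``v_sheet`` (neurons/s) past a neuron at
    location 0; the neuron spikes whenever it lies inside the bump, subject
    to a refractory period.  Each initial theta phase represents one lap.
    Returns per lap (spike times ms, spike phases deg); phase 0 is the
    inhibitory-drive trough.
    """
    cfg = config or SimulationConfig()
    p = resolve_params(cfg, "run")
    slope, intercept = diameter_law
    f = p.f_theta
    if initial_phases_deg is None:
        initial_phases_deg = np.arange(0.0, 360.0, 30.0)
    d_max = max(slope * (p.a_mag_inh - p.a_theta_inh) + intercept,
                slope * (p.a_mag_inh + p.a_theta_inh) + intercept)
    t_span = margin * d_max / max(v_sheet, 1e-9) * 1000.0
    t = np.arange(-t_span / 2.0, t_span / 2.0, dt_ms)
    center = v_sheet * t / 1000.0  # bump center passes the neuron at t=0
    out = []
    for psi_deg in np.atleast_1d(initial_phases_deg):
        psi = np.deg2rad(psi_deg)
        a_inh = p.a_mag_inh - p.a_theta_inh * np.cos(2 * np.pi * f * t / 1000.0 + psi)
        diam = np.clip(slope * a_inh + intercept, 0.0, None)
        inside = np.abs(center) <= diam / 2.0
        spike_t, last = [], -np.inf
        for ti, ok in zip(t, inside):
            if ok and ti - last >= refractory_ms:
                spike_t.append(ti)
                last = ti
        spike_t = np.asarray(spike_t)
        phase = (np.rad2deg(2 * np.pi * f * spike_t / 1000.0 + psi)) % 360.0
        out.append((spike_t, phase))
    return out


def simulate_poisson_pass(
    average_bump: AverageBump,
    max_rate_hz: float,
    v_sheet: float,
    seed: int | np.random.Generator = 0,
    refractory_ms: float = 40.0,
    n_laps: int = 12,
    f_theta: float = 8.0,
    dt_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic rate model: spiking proportional to average bump activity.

    The phase-resolved axis profile of the average bump, rescaled to peak at
    ``max_rate_hz``, drives an inhomogeneous point process (with
    refractoriness) in a neuron the bump passes at sheet speed ``v_sheet``.
    Pools spikes over laps with rotating initial phases.  Returns
    (times ms, phases deg).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profile = average_bump.axis_profile
    peak = profile.max()
    if peak <= 0 or max_rate_hz <= 0:
        return np.zeros(0), np.zeros(0)
    rate_map = profile / peak * max_rate_hz  # (n_phase, n_offset)
    offsets = average_bump.offsets
    n_phase = len(average_bump.phase_centers_deg)
    span = (offsets[-1] - offsets[0]) / max(v_sheet, 1e-9) * 1000.0
    t = np.arange(-span / 2.0, span / 2.0, dt_ms)
    pos = v_sheet * t / 1000.0
    cycle_ms = 1000.0 / f_theta
    times, phases = [], []
    for lap in range(n_laps):
        psi_deg = lap * 360.0 / n_laps
        ph = (360.0 * t / cycle_ms + psi_deg) % 360.0
        pb = np.minimum((ph / 360.0 * n_phase).astype(int), n_phase - 1)
        ob = np.clip(np.round(pos - offsets[0]).astype(int), 0, len(offsets) - 1)
        rate = rate_map[pb, ob]
        u = rng.random(len(t))
        last = -np.inf
        for i in range(len(t)):
            if u[i] < rate[i] * dt_ms / 1000.0 and t[i] - last >= refractory_ms:
                times.append(t[i])
                phases.append(ph[i])
                last = t[i]
    return np.asarray(times), np.asarray(phases)
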