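"""Bayesian population decoding of track position and theta-sequence averaging.

Position is decoded from recorded spike counts under the standard
independent-Poisson model with a uniform prior:

    P(x | n) ~ prod_i rate_i(x)^{n_i} * exp(-tau * sum_i rate_i(x)),

computed in log space and normalized over track bins.  Theta sequences are
exposed by averaging decoded densities over quadruplets of consecutive
theta cycles after aligning each quadruplet to the animal's actual position
at its midpoint (and mirroring leftward laps); the theta-sequence speed is
the steepest slope of the averaged decoded position over a sliding window
of half a theta cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .config import BehavioralState
from .recording import FiringFields, ThetaCycles, _keys_of, _neuron_key
from .simulator import SpikeRecord
from .trajectory import Trajectory

__all__ = [
    "DecodedTrajectory",
    "ThetaSequenceSummary",
    "average_theta_quadruplets",
    "bin_spike_counts",
    "decode_position",
    "decode_record",
    "theta_sequence_speed",
]

DEFAULT_BIN_MS = 20.0
DEFAULT_HOP_MS = 5.0
END_EXCLUSION_CM = 10.0
END_EXCLUSION_FRACTION = 0.1


@dataclass
class DecodedTrajectory:
    """Posterior over track bins per time bin, with the ML path attached."""

    bin_centers_ms: np.ndarray     # (T,)
    pos_bins_cm: np.ndarray        # (B,)
    posterior: np.ndarray          # (T, B), rows sum to 1
    ml_pos_cm: np.ndarray          # (T,)
    actual_pos_cm: np.ndarray      # (T,)
    counts: np.ndarray | None = None

    @property
    def mean_pos_cm(self) -> np.ndarray:
        return self.posterior @ self.pos_bins_cm

    def error_cm(self) -> np.ndarray:
        return self.ml_pos_cm - self.actual_pos_cm


@dataclass
class ThetaSequenceSummary:
    """Quadruplet-averaged decoded density and the fitted sequence speed."""

    rel_time_ms: np.ndarray        # (T,) relative to quadruplet start
    rel_pos_cm: np.ndarray         # (R,) relative to actual mid position
    density: np.ndarray            # (T, R), rows sum to 1
    mean_rel_pos: np.ndarray       # (T,)
    n_quadruplets: int
    cycle_ms: float
    speed_mps: float = np.nan
    fit_window_ms: tuple[float, float] | None = None
    error_vs_phase: tuple[np.ndarray, np.ndarray] | None = None


def decode_position(
    counts: np.ndarray,
    rates: np.ndarray,
    tau_s: float,
) -> np.ndarray:
    """Posterior over positions for each time bin (log-space computation).

    ``counts`` is (T, N) spike counts, ``rates`` (N, B) expected rates in
    spikes/s, ``tau_s`` the bin width in seconds.
    """
    counts = np.asarray(counts, dtype=float)
    rates = np.asarray(rates, dtype=float)
    log_rates = np.log(np.clip(rates, 1e-12, None))
    log_post = counts @ log_rates - tau_s * rates.sum(axis=0)[None, :]
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    return np.exp(log_post)


def bin_spike_counts(
    record: SpikeRecord,
    neurons: np.ndarray,
    bin_ms: float = DEFAULT_BIN_MS,
    hop_ms: float = DEFAULT_HOP_MS,
    step_range: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window spike counts per recorded neuron.

    Returns (bin centers in ms, counts (T, N)).
    """
    keys = _keys_of(np.asarray(neurons, dtype=np.int64))
    order = np.argsort(keys)
    sorted_keys = keys[order]
    spike_keys = _neuron_key(record)
    idx = np.searchsorted(sorted_keys, spike_keys)
    idx = np.clip(idx, 0, len(keys) - 1)
    match = sorted_keys[idx] == spike_keys
    rows = order[idx]

    t = record.step * record.dt
    if step_range is None:
        lo, hi = 0.0, float(record.step.max() + 1) * record.dt if record.step.size else 0.0
    else:
        lo, hi = step_range[0] * record.dt, step_range[1] * record.dt
    sel = match & (t >= lo) & (t < hi)
    t_sel, rows_sel = t[sel], rows[sel]

    starts = np.arange(lo, hi - bin_ms + 1e-9, hop_ms)
    centers = starts + bin_ms / 2.0
    counts = np.zeros((len(starts), len(keys)))
    # each spike lands in every overlapping window
    n_cover = int(np.ceil(bin_ms / hop_ms))
    first = np.floor((t_sel - lo - bin_ms + hop_ms) / hop_ms).astype(int)
    for j in range(n_cover):
        w = first + j
        ok = (w >= 0) & (w < len(starts))
        ok &= (t_sel >= starts[np.clip(w, 0, len(starts) - 1)]) & (
            t_sel < starts[np.clip(w, 0, len(starts) - 1)] + bin_ms
        )
        np.add.at(counts, (w[ok], rows_sel[ok]), 1.0)
    return centers, counts


def decode_record(
    record: SpikeRecord,
    trajectory: Trajectory,
    fields: FiringFields,
    state: BehavioralState | int = BehavioralState.RUN,
    bin_ms: float = DEFAULT_BIN_MS,
    hop_ms: float = DEFAULT_HOP_MS,
) -> DecodedTrajectory:
    """Decode every time bin whose center falls in the requested state."""
    centers, counts = bin_spike_counts(record, fields.neurons, bin_ms, hop_ms,
                                       step_range=(0, trajectory.n_steps))
    post = decode_position(counts, fields.rate, bin_ms / 1000.0)
    step_of = np.clip((centers / trajectory.dt).astype(int), 0, trajectory.n_steps - 1)
    keep = trajectory.state[step_of] == int(state)
    pos = np.atleast_2d(trajectory.pos.T).T[:, 0]
    return DecodedTrajectory(
        bin_centers_ms=centers[keep],
        pos_bins_cm=fields.bin_centers,
        posterior=post[keep],
        ml_pos_cm=fields.bin_centers[np.argmax(post[keep], axis=1)],
        actual_pos_cm=pos[step_of[keep]],
        counts=counts[keep],
    )


def average_theta_quadruplets(
    decoded: DecodedTrajectory,
    cycles: ThetaCycles,
    trajectory: Trajectory,
    n_cycles_per_window: int = 4,
    end_exclusion_cm: float = END_EXCLUSION_CM,
    end_exclusion_fraction: float = END_EXCLUSION_FRACTION,
    hop_ms: float = DEFAULT_HOP_MS,
) -> ThetaSequenceSummary:
    """Average decoded densities over quadruplets of consecutive theta cycles.

    Quadruplets whose decoded (ML) position approaches either track end in
    more than ``end_exclusion_fraction`` of their bins are discarded;
    leftward-lap quadruplets are position-reversed so that forward motion
    always points toward positive relative position; each quadruplet is
    shifted by the actual position at its midpoint before averaging.
    """
    L = trajectory.track_length_cm
    dt = trajectory.dt
    cycle_ms = 1000.0 / 8.0
    # infer the cycle length from labeled cycles when available
    if cycles.trough_steps.size >= 2:
        diffs = np.diff(cycles.trough_steps) * dt
        cycle_ms = float(np.median(diffs[diffs < 2 * np.median(diffs)]))
    bin_cm = float(np.mean(np.diff(decoded.pos_bins_cm)))
    n_rel = int(np.ceil(L / bin_cm))
    rel_pos = (np.arange(2 * n_rel + 1) - n_rel) * bin_cm
    window_ms = n_cycles_per_window * cycle_ms
    n_t = int(round(window_ms / hop_ms))
    rel_t = (np.arange(n_t) + 0.5) * hop_ms

    acc = np.zeros((n_t, len(rel_pos)))
    hits = np.zeros(n_t)
    n_used = 0
    pos_full = np.atleast_2d(trajectory.pos.T).T[:, 0]
    direction = trajectory.direction

    troughs = cycles.trough_steps
    bin_t = decoded.bin_centers_ms
    for i in range(len(troughs) - n_cycles_per_window):
        k0, k1 = troughs[i], troughs[i + n_cycles_per_window]
        # all cycles in the window must be labeled (consecutive, same run)
        if cycles.cycle_of_step[k0] < 0 or cycles.cycle_of_step[k1 - 1] < 0:
            continue
        if np.any(np.diff(troughs[i : i + n_cycles_per_window + 1]) * dt > 1.5 * cycle_ms):
            continue
        t0, t1 = k0 * dt, k1 * dt
        sel = np.nonzero((bin_t >= t0) & (bin_t < t1))[0]
        if len(sel) < 0.8 * n_t:
            continue
        ml = decoded.ml_pos_cm[sel]
        near_end = (ml < end_exclusion_cm) | (ml > L - end_exclusion_cm)
        if near_end.mean() > end_exclusion_fraction:
            continue
        mid_step = int((k0 + k1) // 2)
        d = direction[mid_step]
        if d == 0:
            continue
        actual_mid = pos_full[mid_step]
        post = decoded.posterior[sel]
        axis = decoded.pos_bins_cm
        if d < 0:  # mirror leftward laps
            post = post[:, ::-1]
            axis = L - axis[::-1]
            actual_mid = L - actual_mid
        # shift into relative-position bins
        shift = np.round((axis - actual_mid) / bin_cm).astype(int) + n_rel
        ok = (shift >= 0) & (shift < len(rel_pos))
        ti = np.clip(((bin_t[sel] - t0) / hop_ms).astype(int), 0, n_t - 1)
        for row, tb in enumerate(ti):
            acc[tb, shift[ok]] += post[row, ok]
            hits[tb] += 1
        n_used += 1

    density = np.zeros_like(acc)
    nz = hits > 0
    density[nz] = acc[nz]
    row_sums = density.sum(axis=1, keepdims=True)
    np.divide(density, row_sums, out=density, where=row_sums > 0)
    mean_rel = _ridge_follow(rel_t, rel_pos, density)

    summary = ThetaSequenceSummary(
        rel_time_ms=rel_t, rel_pos_cm=rel_pos, density=density,
        mean_rel_pos=mean_rel, n_quadruplets=n_used, cycle_ms=cycle_ms,
    )
    if n_used >= 1:
        speed, win = theta_sequence_speed(summary, hop_ms=hop_ms)
        summary.speed_mps = speed
        summary.fit_window_ms = win
    return summary


def _ridge_follow(
    t: np.ndarray,
    pos: np.ndarray,
    density: np.ndarray,
    half_window_cm: float = 20.0,
    n_iter: int = 4,
) -> np.ndarray:
    """Local decoded-position estimate that tracks the density ridge.

    The plain density mean is shrunk toward zero by diffuse posterior mass
    far from the animal; instead the mean is taken in a window that is
    iteratively re-centered on the linear trend of the previous estimate,
    which keeps the estimate local to the sweep without biasing its slope.
    """
    center = np.zeros_like(t, dtype=float)
    m = density @ pos
    for _ in range(n_iter):
        for i in range(len(t)):
            sel = np.abs(pos - center[i]) <= half_window_cm
            w = density[i, sel]
            tot = w.sum()
            if tot > 0:
                m[i] = float(w @ pos[sel] / tot)
        good = np.isfinite(m)
        if good.sum() < 2:
            break
        trend = np.polyfit(t[good], m[good], 1)
        center = np.polyval(trend, t)
    return m


def theta_sequence_speed(
    summary: ThetaSequenceSummary,
    window_ms: float | None = None,
    hop_ms: float = DEFAULT_HOP_MS,
) -> tuple[float, tuple[float, float]]:
    """Steepest-increase slope of the averaged decoded position, in m/s.

    A window of half a theta cycle slides across the averaged quadruplet at
    bin resolution; the ordinary-least-squares slope is maximized over
    window placements.  cm/ms slopes convert to m/s by a factor of 10.
    """
    if window_ms is None:
        window_ms = summary.cycle_ms / 2.0
    t = summary.rel_time_ms
    r = summary.mean_rel_pos
    w = max(3, int(round(window_ms / hop_ms)))
    best_slope, best_win = -np.inf, (t[0], t[min(w, len(t)) - 1])
    for i in range(0, len(t) - w + 1):
        tt, rr = t[i : i + w], r[i : i + w]
        slope = np.polyfit(tt, rr, 1)[0]
        if slope > best_slope:
            best_slope = slope
            best_win = (float(tt[0]), float(tt[-1]))
    return float(best_slope * 10.0), best_win


def sequence_error_trace(
    summary: ThetaSequenceSummary,
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged decoded-position offset versus theta phase (one cycle).

    Negative values at cycle boundaries (decoding lags the animal) and
    positive values midcycle (decoding leads) are the theta-sequence
    signature.  The linear trend of forward motion across the quadruplet is
    removed before folding.
    """
    t = summary.rel_time_ms
    r = summary.mean_rel_pos
    trend = np.polyfit(t, r, 1)
    resid = r - np.polyval(trend, t)
    phase = (t / summary.cycle_ms % 1.0) * 360.0
    order = np.argsort(phase)
    return phase[order], resid[order]
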