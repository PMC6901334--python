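"""Multiunit-recording emulation and spatial/theta bookkeeping.

Mimics tetrode sampling of the sheet: neurons are drawn from four circular
regions at a fixed distance from the sheet center (two interleaved sets,
offset 45 degrees), filtered for lap-to-lap field stability, and summarized
as occupancy-normalized firing-rate maps along the track.  Theta cycles are
labeled from the known inhibitory-drive trace, with phase 0 at drive troughs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .config import BehavioralState, SimulationConfig
from .simulator import SpikeRecord
from .trajectory import Trajectory

__all__ = [
    "FiringFields",
    "RecordingSet",
    "ThetaCycles",
    "compute_rate_maps",
    "label_theta",
    "rate_map_autocorrelation",
    "recording_index",
    "select_recording_regions",
    "select_stable_neurons",
    "theta_mua",
]


@dataclass
class RecordingSet:
    """Four recording regions and the stable neurons selected from them."""

    set_id: str
    centers: np.ndarray                  # (4, 2) sheet (y, x)
    region_radius: float
    neurons: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=int))
    usable: bool = True

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)


def select_recording_regions(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence = 0,
    set_id: str = "A",
    radius: float | None = None,
    region_radius: float = 12.0,
) -> RecordingSet:
    """Four region centers at equal angular spacing on a ring.

    The ring radius defaults to 95 neurons from the sheet center (scaled
    down proportionally on sheets too small to hold it).  The common angular
    offset is random; set "B" is rotated 45 degrees from set "A" of the same
    seed.
    """
    n = config.n
    if radius is None:
        radius = 95.0
        max_r = n / 2.0 - region_radius - 1.0
        if radius > max_r:
            radius = max_r * 95.0 / (116.0 - region_radius - 1.0)
    if radius + region_radius >= n / 2.0:
        raise ValueError("recording ring does not fit on the sheet")
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.0, 2.0 * np.pi)
    if set_id == "B":
        base += np.pi / 4.0
    elif set_id != "A":
        raise ValueError("set_id must be 'A' or 'B'")
    angles = base + np.arange(4) * np.pi / 2.0
    cy = cx = (n - 1) / 2.0
    centers = np.stack(
        [cy + radius * np.sin(angles), cx + radius * np.cos(angles)], axis=1
    )
    return RecordingSet(set_id=set_id, centers=centers, region_radius=region_radius)


def recording_index(
    config: SimulationConfig, regions: RecordingSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(population, y, x) index arrays of every excitatory neuron in the regions."""
    n = config.n
    yy, xx = np.mgrid[0:n, 0:n]
    mask = np.zeros((n, n), dtype=bool)
    for cy, cx in regions.centers:
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= regions.region_radius ** 2
    ys, xs = np.nonzero(mask)
    pops = np.repeat(np.arange(4), ys.size)
    return pops.astype(np.intp), np.tile(ys, 4).astype(np.intp), np.tile(xs, 4).astype(np.intp)


def merge_indices(*indices) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Union of (pop, y, x) index triples, deduplicated."""
    pops = np.concatenate([ix[0] for ix in indices])
    ys = np.concatenate([ix[1] for ix in indices])
    xs = np.concatenate([ix[2] for ix in indices])
    key = np.unique(np.stack([pops, ys, xs], axis=1), axis=0)
    return key[:, 0], key[:, 1], key[:, 2]


# ----------------------------------------------------------------- fields

@dataclass
class FiringFields:
    """Track rate maps, detected firing fields, and per-neuron metadata."""

    neurons: np.ndarray          # (N, 3) int: population, y, x
    bin_centers: np.ndarray      # cm
    rate: np.ndarray             # (N, B) spikes/s, smoothed
    occupancy_s: np.ndarray      # (B,) seconds
    fields: list                 # per neuron: list of (lo_cm, hi_cm)
    bin_cm: float

    @property
    def n_fields(self) -> np.ndarray:
        return np.array([len(f) for f in self.fields])

    def field_span(self, neuron: int) -> tuple[float, float] | None:
        """Boundaries of the neuron's dominant (highest-rate) field."""
        if not self.fields[neuron]:
            return None
        best, score = None, -1.0
        for lo, hi in self.fields[neuron]:
            sel = (self.bin_centers >= lo) & (self.bin_centers <= hi)
            peak = self.rate[neuron, sel].max() if sel.any() else 0.0
            if peak > score:
                best, score = (lo, hi), peak
        return best

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (p, y, x) in enumerate(self.neurons):
            span = self.field_span(i)
            rows.append({
                "neuron": i, "population": int(p), "y": int(y), "x": int(x),
                "peak_rate": float(self.rate[i].max()),
                "n_fields": len(self.fields[i]),
                "field_lo_cm": span[0] if span else np.nan,
                "field_hi_cm": span[1] if span else np.nan,
            })
        return pd.DataFrame(rows)


def _neuron_key(record: SpikeRecord) -> np.ndarray:
    return (record.pop.astype(np.int64) << 32) | (record.y.astype(np.int64) << 16) | record.x.astype(np.int64)


def _keys_of(neurons: np.ndarray) -> np.ndarray:
    arr = np.asarray(neurons, dtype=np.int64)
    return (arr[:, 0] << 32) | (arr[:, 1] << 16) | arr[:, 2]


def spike_table(record: SpikeRecord, trajectory: Trajectory) -> pd.DataFrame:
    """Per-spike table with position, state, lap, and direction attached."""
    step = record.step
    pos = np.atleast_2d(trajectory.pos.T).T[:, 0]
    return pd.DataFrame({
        "key": _neuron_key(record),
        "pop": record.pop,
        "y": record.y,
        "x": record.x,
        "step": step,
        "t_ms": record.t_ms,
        "pos_cm": pos[step],
        "state": trajectory.state[step],
        "lap": trajectory.lap_index[step],
        "direction": trajectory.direction[step],
    })


def compute_rate_maps(
    record: SpikeRecord,
    trajectory: Trajectory,
    neurons: np.ndarray,
    bin_cm: float = 2.0,
    smooth_cm: float = 4.0,
    field_threshold: float = 0.2,
    min_field_cm: float = 4.0,
) -> FiringFields:
    """Occupancy-normalized, Gaussian-smoothed rate maps from run spikes.

    Fields accrue from all laps in both directions.  A firing field is a
    contiguous stretch of bins above ``field_threshold`` of the neuron's
    peak rate, at least ``min_field_cm`` wide.
    """
    L = trajectory.track_length_cm
    edges = np.arange(0.0, L + bin_cm, bin_cm)
    centers = 0.5 * (edges[:-1] + edges[1:])
    run = trajectory.run_mask()
    pos = np.atleast_2d(trajectory.pos.T).T[:, 0]
    occ_counts, _ = np.histogram(pos[run], bins=edges)
    dt_s = trajectory.dt / 1000.0
    occupancy = occ_counts * dt_s
    occ_safe = occupancy.copy()
    zero = occupancy <= 0
    if zero.any():  # interpolate rates over unvisited bins
        occ_safe[zero] = np.nan

    neurons = np.asarray(neurons, dtype=np.int64)
    keys = _keys_of(neurons)
    spike_keys = _neuron_key(record)
    run_spike = run[record.step]
    sigma_bins = smooth_cm / bin_cm

    rate = np.zeros((len(neurons), len(centers)))
    order = np.argsort(keys)
    sorted_keys = keys[order]
    idx_of = np.searchsorted(sorted_keys, spike_keys)
    idx_of = np.clip(idx_of, 0, len(keys) - 1)
    match = (sorted_keys[idx_of] == spike_keys) & run_spike
    neuron_row = order[idx_of]
    spos = pos[record.step]
    for row, p in zip(neuron_row[match], spos[match]):
        b = int(p / bin_cm)
        if 0 <= b < len(centers):
            rate[row, b] += 1.0

    with np.errstate(invalid="ignore"):
        rate = rate / occ_safe
    for i in range(rate.shape[0]):  # fill unvisited bins by interpolation
        bad = ~np.isfinite(rate[i])
        if bad.any():
            if bad.all():
                rate[i] = 0.0
            else:
                rate[i, bad] = np.interp(centers[bad], centers[~bad], rate[i, ~bad])
    rate = ndimage.gaussian_filter1d(rate, sigma_bins, axis=1, mode="nearest")

    fields = []
    min_bins = max(1, int(round(min_field_cm / bin_cm)))
    for i in range(rate.shape[0]):
        segs = []
        peak = rate[i].max()
        if peak > 0:
            above = rate[i] >= field_threshold * peak
            lab, nlab = ndimage.label(above)
            for j in range(1, nlab + 1):
                sel = np.nonzero(lab == j)[0]
                if len(sel) >= min_bins:
                    segs.append((edges[sel[0]], edges[sel[-1] + 1]))
        fields.append(segs)

    return FiringFields(
        neurons=neurons, bin_centers=centers, rate=rate,
        occupancy_s=occupancy, fields=fields, bin_cm=bin_cm,
    )


def select_stable_neurons(
    record: SpikeRecord,
    trajectory: Trajectory,
    regions: RecordingSet,
    config: SimulationConfig,
    max_neurons: int = 150,
    stability_cm: float = 10.0,
    min_peak_rate: float = 1.0,
    min_specificity: float = 2.0,
    min_spikes_per_lap: int = 2,
    min_active_lap_fraction: float = 0.5,
    bin_cm: float = 2.0,
) -> RecordingSet:
    """Keep neurons whose dominant-field peak is reproducible across laps.

    A neuron qualifies if it is active on at least half of the laps, the
    s.d. of its per-lap peak position (within a window around the overall
    dominant field) is below ``stability_cm``, its overall peak rate
    exceeds ``min_peak_rate``, and the peak stands out against the map mean
    by at least ``min_specificity`` (spatially unselective neurons have no
    field to be stable about).  Up to ``max_neurons`` are kept, most stable
    first.
    """
    out = RecordingSet(
        set_id=regions.set_id, centers=regions.centers,
        region_radius=regions.region_radius,
    )
    idx = recording_index(config, regions)
    candidates = np.stack(idx, axis=1)
    ff = compute_rate_maps(record, trajectory, candidates, bin_cm=bin_cm)
    table = spike_table(record, trajectory)
    table = table[table.state == int(BehavioralState.RUN)]
    cand_keys = _keys_of(candidates)
    key_to_row = {int(k): i for i, k in enumerate(cand_keys)}

    n_laps = trajectory.n_laps
    peak_pos = ff.bin_centers[np.argmax(ff.rate, axis=1)]
    lap_peaks: dict[int, list[float]] = {i: [] for i in range(len(candidates))}
    for (key, lap), grp in table.groupby(["key", "lap"], sort=False):
        row = key_to_row.get(int(key))
        if row is None or len(grp) < min_spikes_per_lap:
            continue
        p = grp.pos_cm.to_numpy()
        near = np.abs(p - peak_pos[row]) <= 20.0  # stay within the dominant field
        if near.sum() >= min_spikes_per_lap:
            lap_peaks[row].append(float(np.median(p[near])))

    spread = np.full(len(candidates), np.inf)
    for row, peaks in lap_peaks.items():
        if len(peaks) >= max(2, int(np.ceil(min_active_lap_fraction * n_laps))):
            spread[row] = float(np.std(peaks))
    mean_rate = ff.rate.mean(axis=1)
    specific = ff.rate.max(axis=1) >= min_specificity * np.maximum(mean_rate, 1e-12)
    ok = (spread < stability_cm) & (ff.rate.max(axis=1) > min_peak_rate) & specific
    chosen = np.nonzero(ok)[0]
    chosen = chosen[np.argsort(spread[chosen])][:max_neurons]
    out.neurons = candidates[np.sort(chosen)]
    if len(out.neurons) < 10:
        out.usable = False
    return out


def rate_map_autocorrelation(map2d: np.ndarray) -> np.ndarray:
    """Normalized 2D spatial autocorrelation (1 at zero lag)."""
    m = np.asarray(map2d, dtype=float)
    m = m - m.mean()
    ac = signal.fftconvolve(m, m[::-1, ::-1], mode="same")
    peak = ac.max()
    return ac / peak if peak > 0 else ac


# ------------------------------------------------------------------ theta

@dataclass
class ThetaCycles:
    """Theta-cycle boundaries and a per-timestep phase trace.

    Phase is 0 degrees at troughs of the inhibitory drive and advances
    linearly to 360 at the next trough; NaN outside theta-labeled segments.
    """

    dt: float
    trough_steps: np.ndarray       # step indices of drive troughs
    phase_deg: np.ndarray          # (T,) float, NaN where unlabeled
    cycle_of_step: np.ndarray      # (T,) int32 cycle id, -1 where unlabeled

    @property
    def n_cycles(self) -> int:
        return int(self.cycle_of_step.max()) + 1 if self.cycle_of_step.size else 0

    def boundaries_ms(self) -> np.ndarray:
        return self.trough_steps * self.dt


def label_theta(
    drive_trace: np.ndarray,
    dt: float,
    segment_mask: np.ndarray | None = None,
    f_theta: float = 8.0,
) -> ThetaCycles:
    """Label theta cycles from troughs of the oscillating inhibitory drive.

    Only segments where the drive actually oscillates are labeled; phase is
    linear in time within each trough-to-trough cycle and extrapolated at
    the period 1/f over partial cycles at segment edges.
    """
    trace = np.asarray(drive_trace, dtype=float)
    T = len(trace)
    phase = np.full(T, np.nan)
    cycle_of = np.full(T, -1, dtype=np.int32)
    if segment_mask is None:
        segment_mask = np.ones(T, dtype=bool)
    period = 1000.0 / f_theta / dt  # steps
    troughs_all = []
    cycle_id = 0
    lab, nseg = ndimage.label(segment_mask)
    for s in range(1, nseg + 1):
        sel = np.nonzero(lab == s)[0]
        seg = trace[sel]
        if seg.max() - seg.min() < 1e-6:
            continue  # no oscillation here (idle-like segment)
        troughs, _ = signal.find_peaks(-seg, distance=max(2, int(period * 0.6)))
        if len(troughs) == 0:
            continue
        t_idx = sel[0] + np.asarray(troughs)
        rel = np.arange(len(seg), dtype=float)
        ph = np.empty(len(seg))
        ph[: troughs[0]] = 360.0 * ((rel[: troughs[0]] - troughs[0]) / period % 1.0)
        for a, b in zip(troughs[:-1], troughs[1:]):
            ph[a:b] = 360.0 * (rel[a:b] - a) / (b - a)
        ph[troughs[-1]:] = 360.0 * ((rel[troughs[-1]:] - troughs[-1]) / period % 1.0)
        phase[sel] = ph
        # full cycles only get ids
        for a, b in zip(troughs[:-1], troughs[1:]):
            cycle_of[sel[0] + a : sel[0] + b] = cycle_id
            cycle_id += 1
        troughs_all.extend(t_idx.tolist())
    return ThetaCycles(
        dt=dt,
        trough_steps=np.asarray(troughs_all, dtype=np.int64),
        phase_deg=phase,
        cycle_of_step=cycle_of,
    )


def theta_mua(
    record: SpikeRecord,
    cycles: ThetaCycles,
    n_bins: int = 24,
) -> tuple[np.ndarray, np.ndarray]:
    """Cycle-averaged multiunit activity versus theta phase.

    Returns (phase bin centers in degrees, mean spikes per cycle per bin).
    """
    ph = cycles.phase_deg[record.step]
    valid = np.isfinite(ph) & (cycles.cycle_of_step[record.step] >= 0)
    n_cycles = max(1, cycles.n_cycles)
    hist, edges = np.histogram(ph[valid], bins=n_bins, range=(0.0, 360.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist / n_cycles
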