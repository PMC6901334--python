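"""Theta-phase versus position statistics for single neurons.

Circular-linear regression finds the slope ``a`` maximizing the mean
resultant length R(a) = |mean_j exp(i(phi_j - a x_j))| of the phase
residuals; the fit score is R at the optimum, and the (signed)
circular-linear correlation follows the circular-circular correlation
between measured phases and the fitted linear predictor.  Neurons are
classified as phase-independent (low fit score), phase-locking (good fit,
shallow slope), or phase-precessing (good fit, precession range of at least
60 degrees per field).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PhaseStats",
    "circular_linear_correlation",
    "circular_linear_regression",
    "classify_phase_behavior",
    "density_ridge",
    "directionality_and_speed_stratification",
    "phase_samples",
    "spike_density_map",
]

FIT_SCORE_CUTOFF = 0.4
PRECESSION_RANGE_CUTOFF = 60.0  # degrees per field
# Slope search bound: one theta cycle per field (360 deg / 100 %).  Wider
# bounds admit an alias: within a single pass, phase advances a full cycle
# per ~6 cm of travel, so phase-vs-progress has a spurious ramp of about
# 0.58 * field_width(cm) deg/% that a wider search locks onto.
SLOPE_BOUND = 3.6               # deg per % progress
MIN_SPIKES = 5


@dataclass
class PhaseStats:
    """Per-neuron (and per-direction) circular-linear summary."""

    n_spikes: int
    slope: float          # deg per % field progress
    offset: float         # deg, circular mean residual
    fit_score: float      # mean resultant length at the optimal slope
    corr: float           # signed circular-linear correlation
    subgroup: str         # independent | locking | precessing

    @property
    def precession_range(self) -> float:
        return abs(self.slope) * 100.0


def _resultant(phases_rad: np.ndarray, x: np.ndarray, slope_rad: float) -> float:
    z = np.exp(1j * (phases_rad - slope_rad * x))
    return float(np.abs(z.mean()))


def circular_linear_regression(
    phases_deg: np.ndarray,
    positions: np.ndarray,
    slope_bound: float = SLOPE_BOUND,
    coarse_step: float = 0.05,
) -> tuple[float, float, float]:
    """Fit phase = slope * position + offset (circular in phase).

    ``positions`` are in % of field progress (0-100); the returned slope is
    in degrees per %.  The search maximizes the mean resultant length over a
    bounded slope range (coarse grid then local refinement) to avoid slope
    aliasing.  Returns (slope_deg_per_pct, offset_deg, fit_score).
    """
    phases = np.asarray(phases_deg, dtype=float)
    x = np.asarray(positions, dtype=float)
    if len(phases) < MIN_SPIKES:
        raise ValueError(f"need at least {MIN_SPIKES} spikes for regression")
    phr = np.deg2rad(phases)
    grid = np.arange(-slope_bound, slope_bound + coarse_step, coarse_step)
    grid_rad = np.deg2rad(grid)
    # vectorized resultant over the slope grid
    z = np.exp(1j * (phr[None, :] - grid_rad[:, None] * x[None, :]))
    r = np.abs(z.mean(axis=1))
    best = int(np.argmax(r))
    lo = grid_rad[max(0, best - 1)]
    hi = grid_rad[min(len(grid) - 1, best + 1)]
    res = optimize.minimize_scalar(
        lambda a: -_resultant(phr, x, a), bounds=(lo, hi), method="bounded",
        options={"xatol": np.deg2rad(1e-4)},
    )
    a_star = float(res.x)
    score = _resultant(phr, x, a_star)
    resid = phr - a_star * x
    offset = float(np.rad2deg(np.angle(np.exp(1j * resid).mean())) % 360.0)
    return float(np.rad2deg(a_star)), offset, score


def circular_linear_correlation(
    phases_deg: np.ndarray,
    positions: np.ndarray,
    slope_deg_per_pct: float | None = None,
) -> float:
    """Signed correlation between spike phases and the fitted linear predictor.

    Circular-circular correlation between phi_j and psi_j = slope * x_j; the
    slope is fitted first when not supplied.  Zero positional variance is an
    error; a zero fitted slope gives zero correlation by convention.
    """
    phases = np.asarray(phases_deg, dtype=float)
    x = np.asarray(positions, dtype=float)
    if len(phases) < MIN_SPIKES:
        raise ValueError(f"need at least {MIN_SPIKES} spikes")
    if np.ptp(x) == 0:
        raise ValueError("zero positional variance; correlation undefined")
    if slope_deg_per_pct is None:
        slope_deg_per_pct, _, _ = circular_linear_regression(phases, x)
    phi = np.deg2rad(phases)
    psi = np.deg2rad(slope_deg_per_pct * x)
    dphi = np.sin(phi - np.angle(np.exp(1j * phi).mean()))
    dpsi = np.sin(psi - np.angle(np.exp(1j * psi).mean()))
    denom = np.sqrt((dphi ** 2).sum() * (dpsi ** 2).sum())
    if denom == 0:
        return 0.0
    return float((dphi * dpsi).sum() / denom)


def classify_phase_behavior(
    fit_score: float,
    slope_deg_per_pct: float,
    fit_cutoff: float = FIT_SCORE_CUTOFF,
    range_cutoff: float = PRECESSION_RANGE_CUTOFF,
) -> str:
    """independent (poor fit), precessing (range >= cutoff), else locking."""
    if fit_score < fit_cutoff:
        return "independent"
    if abs(slope_deg_per_pct) * 100.0 >= range_cutoff:
        return "precessing"
    return "locking"


def phase_stats(
    phases_deg: np.ndarray, positions: np.ndarray
) -> PhaseStats:
    """Full regression + correlation + classification for one spike sample."""
    slope, offset, score = circular_linear_regression(phases_deg, positions)
    corr = circular_linear_correlation(phases_deg, positions, slope)
    return PhaseStats(
        n_spikes=len(np.asarray(phases_deg)),
        slope=slope, offset=offset, fit_score=score, corr=corr,
        subgroup=classify_phase_behavior(score, slope),
    )


# ------------------------------------------------------------- assembling

def phase_samples(
    spikes: pd.DataFrame,
    fields,
    cycles,
) -> pd.DataFrame:
    """Attach theta phase and field progress to in-field run spikes.

    ``spikes`` is a spike table (see :func:`gridwave.recording.spike_table`)
    restricted to one recording set; ``fields`` a FiringFields over the same
    neurons.  Progress runs from 0 at field entry to 100 at exit, so entry
    is at the low boundary on rightward laps and the high boundary on
    leftward laps.  Spikes inside any of the neuron's firing fields during
    runs, with a labeled theta phase, are kept; progress is relative to the
    field containing the spike.
    """
    from .recording import _keys_of  # shared neuron hashing

    keys = _keys_of(fields.neurons)
    row_of = {int(k): i for i, k in enumerate(keys)}
    rows = []
    for (key,), grp in spikes.groupby(["key"], sort=False):
        row = row_of.get(int(key))
        if row is None or not fields.fields[row]:
            continue
        p = grp.pos_cm.to_numpy()
        phase = cycles.phase_deg[grp.step.to_numpy()]
        base = np.isfinite(phase) & (grp.direction.to_numpy() != 0)
        for fid, (lo, hi) in enumerate(fields.fields[row]):
            width = hi - lo
            if width <= 0:
                continue
            ok = base & (p >= lo) & (p <= hi)
            if not ok.any():
                continue
            d = grp.direction.to_numpy()[ok]
            prog = np.where(d > 0, (p[ok] - lo) / width, (hi - p[ok]) / width) * 100.0
            rows.append(pd.DataFrame({
                "neuron": row,
                "field": fid,
                "phase_deg": phase[ok],
                "pos_cm": p[ok],
                "progress": prog,
                "direction": d,
                "lap": grp.lap.to_numpy()[ok],
                "t_ms": grp.t_ms.to_numpy()[ok],
            }))
    if not rows:
        return pd.DataFrame(
            columns=["neuron", "field", "phase_deg", "pos_cm", "progress",
                     "direction", "lap", "t_ms"]
        )
    return pd.concat(rows, ignore_index=True)


def per_neuron_phase_stats(samples: pd.DataFrame) -> pd.DataFrame:
    """Regression/correlation/classification per (neuron, direction)."""
    rows = []
    for (neuron, direction), grp in samples.groupby(["neuron", "direction"]):
        if len(grp) < MIN_SPIKES or np.ptp(grp.progress.to_numpy()) == 0:
            continue
        st = phase_stats(grp.phase_deg.to_numpy(), grp.progress.to_numpy())
        rows.append({
            "neuron": int(neuron), "direction": int(direction),
            "n_spikes": st.n_spikes, "slope": st.slope, "offset": st.offset,
            "fit_score": st.fit_score, "corr": st.corr,
            "precession_range": st.precession_range, "subgroup": st.subgroup,
        })
    return pd.DataFrame(rows)


def spike_density_map(
    samples: pd.DataFrame,
    progress_bins: int = 20,
    phase_bins: int = 24,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spike density over (field progress, theta phase), normalized to sum 1.

    Returns (density[progress_bin, phase_bin], progress centers, phase
    centers).  Display duplication over two phase cycles is left to plotting.
    """
    h, pe, fe = np.histogram2d(
        samples.progress.to_numpy(), samples.phase_deg.to_numpy(),
        bins=[progress_bins, phase_bins], range=[[0, 100], [0, 360]],
    )
    total = h.sum()
    if total > 0:
        h = h / total
    return h, 0.5 * (pe[:-1] + pe[1:]), 0.5 * (fe[:-1] + fe[1:])


def density_ridge(
    samples: pd.DataFrame,
    progress_edges: np.ndarray | None = None,
    phase_bin_deg: float = 15.0,
    smooth_bins: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak-density (modal) phase per field-progress bin.

    Per progress bin, the phase histogram is smoothed circularly and its
    peak located with sub-bin (parabolic) precision.  Phases are reported
    on the (180, 540] branch so the preferred phase near the theta trough
    appears as ~360 rather than wrapping to 0.  Returns (progress bin
    centers, ridge phase in degrees).
    """
    from scipy import ndimage as _ndi

    if progress_edges is None:
        progress_edges = np.linspace(0, 100, 11)
    prog = samples.progress.to_numpy()
    ph = samples.phase_deg.to_numpy() % 360.0
    edges = np.arange(0.0, 360.0 + phase_bin_deg, phase_bin_deg)
    nb = len(edges) - 1
    mids = edges[:-1] + phase_bin_deg / 2.0
    centers, ridge = [], []
    prev_mode: float | None = None
    for lo, hi in zip(progress_edges[:-1], progress_edges[1:]):
        sel = (prog >= lo) & (prog < hi)
        if sel.sum() < 2 * MIN_SPIKES:
            continue
        hist, _ = np.histogram(ph[sel], bins=edges)
        hist = _ndi.gaussian_filter1d(hist.astype(float), smooth_bins, mode="wrap")
        if prev_mode is None:
            i = int(np.argmax(hist))
        else:
            # the ridge is continuous: restrict the peak search to +/-90
            # degrees of the previous bin's mode, which keeps the track on
            # the precessing ridge rather than any secondary density
            dist = np.abs((mids - prev_mode + 180.0) % 360.0 - 180.0)
            allowed = dist <= 90.0
            masked = np.where(allowed, hist, -np.inf)
            i = int(np.argmax(masked))
        prev_b, next_b = hist[(i - 1) % nb], hist[(i + 1) % nb]
        denom = prev_b - 2 * hist[i] + next_b
        frac = 0.5 * (prev_b - next_b) / denom if denom != 0 else 0.0
        mode = (edges[i] + (0.5 + np.clip(frac, -0.5, 0.5)) * phase_bin_deg) % 360.0
        prev_mode = mode
        if mode <= 180.0:
            mode += 360.0
        centers.append(0.5 * (lo + hi))
        ridge.append(mode)
    ridge_arr = np.asarray(ridge)
    # unwrap along progress so drops across the 540/180 seam stay continuous
    for i in range(1, len(ridge_arr)):
        while ridge_arr[i] - ridge_arr[i - 1] > 180.0:
            ridge_arr[i] -= 360.0
        while ridge_arr[i] - ridge_arr[i - 1] < -180.0:
            ridge_arr[i] += 360.0
    return np.asarray(centers), ridge_arr


def circular_mode(phases_deg: np.ndarray, bin_deg: float = 15.0) -> float:
    """Modal phase via histogram on the (180, 540] branch (360 == 0)."""
    ph = np.asarray(phases_deg, dtype=float) % 360.0
    ph = np.where(ph <= 180.0, ph + 360.0, ph)
    edges = np.arange(180.0, 540.0 + bin_deg, bin_deg)
    hist, _ = np.histogram(ph, bins=edges)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


def directionality_and_speed_stratification(
    samples: pd.DataFrame,
    stats_table: pd.DataFrame,
    run_speed_of_lap: dict[int, float] | None = None,
    n_speed_bins: int = 3,
) -> dict:
    """Slope-sign summary per direction and phase statistics by speed tercile.

    When per-lap speeds are supplied, spikes are split into speed terciles,
    per-(neuron, direction, tercile) statistics recomputed, and the
    Kruskal-Wallis H test applied to precession range and |corr| across
    terciles.
    """
    out: dict = {}
    sign = {}
    for d, grp in stats_table.groupby("direction"):
        good = grp[grp.fit_score >= FIT_SCORE_CUTOFF]
        sign[int(d)] = {
            "n": len(good),
            "frac_negative": float((good.slope < 0).mean()) if len(good) else np.nan,
            "median_slope": float(good.slope.median()) if len(good) else np.nan,
        }
    out["slope_sign_by_direction"] = sign

    if run_speed_of_lap:
        speeds = samples.lap.map(run_speed_of_lap)
        edges = np.quantile(
            np.array(list(run_speed_of_lap.values())), np.linspace(0, 1, n_speed_bins + 1)
        )
        tercile = np.clip(np.searchsorted(edges[1:-1], speeds, side="right"), 0, n_speed_bins - 1)
        rows = []
        for tb in range(n_speed_bins):
            sub = samples[tercile == tb]
            st = per_neuron_phase_stats(sub)
            st["speed_bin"] = tb
            rows.append(st)
        by_speed = pd.concat(rows, ignore_index=True)
        out["by_speed"] = by_speed
        groups_range = [
            g.precession_range.to_numpy()
            for _, g in by_speed[by_speed.fit_score >= FIT_SCORE_CUTOFF].groupby("speed_bin")
        ]
        groups_corr = [np.abs(g["corr"].to_numpy()) for _, g in by_speed.groupby("speed_bin")]
        if len(groups_range) >= 2 and all(len(g) > 0 for g in groups_range):
            h, p = stats.kruskal(*groups_range)
            out["kruskal_range"] = {"H": float(h), "p": float(p)}
        if len(groups_corr) >= 2 and all(len(g) > 0 for g in groups_corr):
            h, p = stats.kruskal(*groups_corr)
            out["kruskal_corr"] = {"H": float(h), "p": float(p)}
    return out
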