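"""Replay detection in idle-period decoded activity.

During quiescence, traveling wavefronts of excitatory spiking sweep across
the recorded regions and are decoded (with the run-derived firing fields)
as rapid, line-like trajectories.  Candidate events are windows of elevated
multiunit activity of the recorded population lasting 50-300 ms; within
each, a robust line is fit to the maximum-likelihood decoded positions, and
events are accepted when the decoded span covers enough of the track with a
good enough fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .decoding import DecodedTrajectory

__all__ = [
    "ReplayEvent",
    "detect_replays",
    "direction_bias",
    "events_frame",
    "fit_replay_line",
    "replay_speed_summary",
]


@dataclass
class ReplayEvent:
    t_start_ms: float
    t_end_ms: float
    speed_mps: float             # |slope|
    slope_mps: float             # signed
    p_start_cm: float            # fitted line at event start
    p_end_cm: float
    r2: float
    direction: str = ""          # away | toward | ambiguous
    animal_pos_cm: float = np.nan
    sim_id: str = ""


def fit_replay_line(
    t_ms: np.ndarray,
    pos_cm: np.ndarray,
    inlier_tol_cm: float = 12.0,
) -> tuple[float, float, float, np.ndarray]:
    """Robust line fit tolerant to decoding-alias outliers.

    A Theil-Sen fit seeds the line; points within ``inlier_tol_cm`` of it
    are inliers, the line is refit to them by ordinary least squares (one
    more inlier pass), and R^2 is evaluated on the final inliers.  Returns
    (slope cm/ms, intercept, R^2, inlier mask).  Decoded idle positions can
    hop between track positions that share a sheet-lattice phase; the
    inlier mechanism extracts the dominant linear branch.
    """
    t = np.asarray(t_ms, dtype=float)
    p = np.asarray(pos_cm, dtype=float)
    slope, intercept, _, _ = stats.theilslopes(p, t)
    inliers = np.abs(p - (intercept + slope * t)) <= inlier_tol_cm
    for _ in range(2):
        if inliers.sum() < 3:
            return float(slope), float(intercept), 0.0, inliers
        slope, intercept = np.polyfit(t[inliers], p[inliers], 1)
        inliers = np.abs(p - (intercept + slope * t)) <= inlier_tol_cm
    pi, ti = p[inliers], t[inliers]
    pred = intercept + slope * ti
    ss_tot = ((pi - pi.mean()) ** 2).sum()
    r2 = 1.0 - ((pi - pred) ** 2).sum() / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(intercept), float(r2), inliers


def detect_replays(
    decoded: DecodedTrajectory,
    track_length_cm: float,
    mua_z_threshold: float = 2.0,
    mua_boundary_z: float = 0.0,
    min_duration_ms: float = 50.0,
    max_duration_ms: float = 300.0,
    min_span_fraction: float = 0.3,
    min_r2: float = 0.5,
    min_inlier_fraction: float = 0.5,
    min_speed_mps: float = 0.5,
    mua_smooth_bins: float = 2.0,
    sim_id: str = "",
) -> list[ReplayEvent]:
    """Detect replay events in idle-period decoded activity.

    ``decoded`` must come from idle segments decoded with run-derived
    fields and carry the per-bin spike ``counts``.  Candidate windows are
    stretches of smoothed multiunit rate above ``mua_boundary_z`` s.d. that
    peak above ``mua_z_threshold`` s.d. (event boundaries extended to the
    lower threshold, as in ripple detection); events are kept when a robust
    line fits the maximum-likelihood positions with enough inliers, span,
    and goodness of fit.
    """
    if decoded.posterior.shape[0] == 0:
        return []
    if decoded.counts is None:
        raise ValueError("decoded trajectory lacks spike counts for MUA detection")
    t = decoded.bin_centers_ms
    mua = decoded.counts.sum(axis=1).astype(float)
    mua = ndimage.gaussian_filter1d(mua, mua_smooth_bins)
    mu, sd = mua.mean(), mua.std()
    if sd == 0:
        return []
    z = (mua - mu) / sd

    # time bins may be discontiguous across idle periods; split on gaps
    hop = np.median(np.diff(t)) if len(t) > 1 else 1.0
    gap = np.diff(t) > 2.5 * hop
    segment = np.concatenate([[0], np.cumsum(gap)])

    events: list[ReplayEvent] = []
    active = z > mua_boundary_z
    lab, nlab = ndimage.label(active)
    for j in range(1, nlab + 1):
        sel = np.nonzero(lab == j)[0]
        if segment[sel[0]] != segment[sel[-1]]:
            continue
        if z[sel].max() < mua_z_threshold:
            continue
        dur = t[sel[-1]] - t[sel[0]] + hop
        if not (min_duration_ms <= dur <= max_duration_ms):
            continue
        ml = decoded.ml_pos_cm[sel]
        slope, intercept, r2, inliers = fit_replay_line(t[sel], ml)
        if inliers.mean() < min_inlier_fraction or r2 < min_r2:
            continue
        span = ml[inliers].max() - ml[inliers].min()
        if span < min_span_fraction * track_length_cm:
            continue
        speed = abs(slope) * 10.0  # cm/ms -> m/s
        if speed < min_speed_mps:
            continue
        p0 = intercept + slope * t[sel[0]]
        p1 = intercept + slope * t[sel[-1]]
        events.append(ReplayEvent(
            t_start_ms=float(t[sel[0]]), t_end_ms=float(t[sel[-1]]),
            speed_mps=speed, slope_mps=float(slope * 10.0),
            p_start_cm=float(np.clip(p0, 0, track_length_cm)),
            p_end_cm=float(np.clip(p1, 0, track_length_cm)),
            r2=r2, animal_pos_cm=float(np.median(decoded.actual_pos_cm[sel])),
            sim_id=sim_id,
        ))
    return events


def replay_speed_summary(events_by_sim: dict[str, list[ReplayEvent]]) -> dict:
    """Pooled replay-speed statistics and per-simulation counts."""
    speeds = np.array([e.speed_mps for evs in events_by_sim.values() for e in evs])
    counts = {sim: len(evs) for sim, evs in events_by_sim.items()}
    if speeds.size == 0:
        return {"n_events": 0, "counts": counts,
                "mean_speed_mps": np.nan, "sd_speed_mps": np.nan}
    return {
        "n_events": int(speeds.size),
        "counts": counts,
        "mean_speed_mps": float(speeds.mean()),
        "sd_speed_mps": float(speeds.std(ddof=1)) if speeds.size > 1 else 0.0,
    }


def label_direction(
    event: ReplayEvent, track_length_cm: float, speed_floor_mps: float = 0.5
) -> str:
    """away/toward the animal's current track end, from the fit-line slope."""
    if abs(event.slope_mps) < speed_floor_mps:
        return "ambiguous"
    at_left = event.animal_pos_cm < track_length_cm / 2.0
    outward = event.slope_mps > 0 if at_left else event.slope_mps < 0
    return "away" if outward else "toward"


def direction_bias(
    events_by_sim: dict[str, list[ReplayEvent]],
    track_length_cm: float,
) -> dict:
    """Directional bias of replay propagation relative to the resting animal.

    Labels each event away/toward, compares per-simulation away vs toward
    counts with the Mann-Whitney U test, and compares start vs end distances
    of the fitted line from the actual position with the Wilcoxon
    signed-rank test.  Intended for low-velocity-gain networks where sheet
    location maps one-to-one onto track position.
    """
    away_counts, toward_counts = [], []
    d_start, d_end = [], []
    for sim, evs in events_by_sim.items():
        a = t = 0
        for e in evs:
            lab = label_direction(e, track_length_cm)
            e.direction = lab
            if lab == "away":
                a += 1
            elif lab == "toward":
                t += 1
            if lab != "ambiguous":
                d_start.append(abs(e.p_start_cm - e.animal_pos_cm))
                d_end.append(abs(e.p_end_cm - e.animal_pos_cm))
        away_counts.append(a)
        toward_counts.append(t)

    out = {
        "away_counts": away_counts,
        "toward_counts": toward_counts,
        "n_away": int(np.sum(away_counts)),
        "n_toward": int(np.sum(toward_counts)),
        "median_start_dist_cm": float(np.median(d_start)) if d_start else np.nan,
        "median_end_dist_cm": float(np.median(d_end)) if d_end else np.nan,
    }
    if len(away_counts) >= 2 and (np.ptp(away_counts) > 0 or np.ptp(toward_counts) > 0):
        u, p = stats.mannwhitneyu(away_counts, toward_counts, alternative="greater")
        out["mannwhitney_u"], out["mannwhitney_p"] = float(u), float(p)
    if len(d_start) >= 5:
        diffs = np.asarray(d_end) - np.asarray(d_start)
        if np.any(diffs != 0):
            w, p = stats.wilcoxon(d_start, d_end, alternative="less")
            out["wilcoxon_w"], out["wilcoxon_p"] = float(w), float(p)
    return out


def events_frame(events_by_sim: dict[str, list[ReplayEvent]]) -> pd.DataFrame:
    rows = []
    for sim, evs in events_by_sim.items():
        for e in evs:
            rows.append({
                "sim_id": sim, "t_start_ms": e.t_start_ms, "t_end_ms": e.t_end_ms,
                "speed_mps": e.speed_mps, "p_start_cm": e.p_start_cm,
                "p_end_cm": e.p_end_cm, "direction": e.direction, "r2": e.r2,
            })
    return pd.DataFrame(rows)
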