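"""Standard diagnostic panels rendered from session results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .session import SessionResult

__all__ = ["render_figures"]


def render_figures(results: list[SessionResult], out_dir: str | Path) -> list[Path]:
    """Render one file per available panel; missing inputs skip with a log.

    Raises if there is nothing at all to draw.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if not results:
        raise ValueError("no session results to render")
    res = results[0]

    # spike raster of the first usable recording set, first laps
    for sid, s in res.sets.items():
        if not s.usable or s.samples is None or s.samples.empty:
            continue
        fig, ax = plt.subplots(figsize=(7, 4))
        samp = s.samples[s.samples.lap < 4]
        ax.scatter(samp.t_ms / 1000.0, samp.neuron, s=2, c="k")
        ax.set(xlabel="time (s)", ylabel="neuron", title=f"set {sid} run raster")
        p = out / f"raster_{res.sim_id or 'run'}_{sid}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
        break

    # phase-position scatter pooled over precessing neurons
    for sid, s in res.sets.items():
        if s.samples is None or s.samples.empty or s.phase_table is None:
            continue
        prec = s.phase_table[s.phase_table.subgroup == "precessing"]
        if prec.empty:
            continue
        sel = s.samples[s.samples.neuron.isin(prec.neuron)]
        fig, ax = plt.subplots(figsize=(5, 4))
        for rep in (0, 360):  # duplicate cycles for display
            ax.scatter(sel.progress, sel.phase_deg + rep, s=2, c="tab:blue")
        ax.set(xlabel="field progress (%)", ylabel="theta phase (deg)",
               title="precessing subgroup")
        p = out / f"phase_scatter_{res.sim_id or 'run'}_{sid}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
        break

    # averaged theta quadruplet
    for sid, s in res.sets.items():
        if s.sequences is None or s.sequences.n_quadruplets == 0:
            continue
        seq = s.sequences
        fig, ax = plt.subplots(figsize=(6, 4))
        extent = [seq.rel_time_ms[0], seq.rel_time_ms[-1],
                  seq.rel_pos_cm[0], seq.rel_pos_cm[-1]]
        ax.imshow(seq.density.T, origin="lower", aspect="auto", extent=extent,
                  cmap="viridis")
        ax.plot(seq.rel_time_ms, seq.mean_rel_pos, "w-", lw=1)
        if seq.fit_window_ms:
            a, b = seq.fit_window_ms
            ax.axvspan(a, b, color="w", alpha=0.15)
        ax.set(xlabel="time in quadruplet (ms)", ylabel="relative position (cm)",
               title=f"theta sequences, {seq.speed_mps:.2f} m/s")
        p = out / f"quadruplet_{res.sim_id or 'run'}_{sid}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
        break

    # replay fit lines
    events = [e for r in results for evs in r.all_replays().values() for e in evs]
    if events:
        fig, ax = plt.subplots(figsize=(6, 4))
        for e in events[:40]:
            ax.plot([0, e.t_end_ms - e.t_start_ms], [e.p_start_cm, e.p_end_cm],
                    c="c", alpha=0.7)
        ax.set(xlabel="time in event (ms)", ylabel="decoded position (cm)",
               title=f"{len(events)} replay events")
        p = out / "replays.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    if not written:
        raise RuntimeError("no panels could be rendered from the given results")
    return written


def snapshot_panel(
    spike_history: np.ndarray, out_path: str | Path, fade_ms: float = 40.0, dt: float = 1.0
) -> Path:
    """Sheet-activity snapshot: darkest for current spikes, fading with age.

    ``spike_history`` is (T, n, n) boolean with the last row most recent.
    """
    T = spike_history.shape[0]
    n_fade = max(1, int(round(fade_ms / dt)))
    hist = spike_history[-n_fade:]
    age = np.arange(hist.shape[0])[::-1]  # 0 = current
    weight = 1.0 - age / n_fade
    img = np.zeros(hist.shape[1:])
    for w, frame in zip(weight[::-1], hist[::-1]):
        img = np.maximum(img, w * frame)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(1.0 - img, cmap="gray", vmin=0, vmax=1, origin="lower")
    ax.set_axis_off()
    out = Path(out_path)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out
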