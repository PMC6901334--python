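"""Replicate-experiment orchestration and pooled summaries.

An experiment manifest lists (config, seed, variant) entries; each entry
runs a full session and writes per-run tables, then a pooled summary of the
population statistics (run and theta-sequence speeds, replay speeds, phase
statistics) is assembled across runs.  All randomness flows from manifest
seeds, so reruns reproduce numeric tables exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .phase import circular_mode, density_ridge
from .replay import events_frame, replay_speed_summary
from .session import SessionResult, run_full_session

__all__ = [
    "ExperimentManifest",
    "ManifestEntry",
    "pool_sessions",
    "run_experiment",
]

log = logging.getLogger("gridwave")


@dataclass
class ManifestEntry:
    run_id: str
    seed: int
    variant: str = "default"
    n_laps: int = 8
    overrides: dict = field(default_factory=dict)

    def build_config(self, base: SimulationConfig | None = None) -> SimulationConfig:
        cfg = (base or SimulationConfig()).variant(self.variant)
        overrides = {k: v for k, v in self.overrides.items() if not k.startswith("_")}
        return cfg.replace(**overrides) if overrides else cfg


@dataclass
class ExperimentManifest:
    entries: list[ManifestEntry]
    base_config: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        seeds = [e.seed for e in self.entries]
        if len(set(seeds)) != len(seeds):
            raise ValueError("manifest seeds must be unique per run")

    @classmethod
    def replicate(
        cls,
        n_runs: int,
        base_seed: int = 0,
        variant: str = "default",
        n_laps: int = 8,
        reversed_pairs: bool = False,
        **overrides,
    ) -> "ExperimentManifest":
        """n_runs sessions with consecutive seeds; optionally paired with
        reversed-velocity twins of the same trajectories."""
        entries = [
            ManifestEntry(f"run{i:02d}", base_seed + i, variant, n_laps, dict(overrides))
            for i in range(n_runs)
        ]
        if reversed_pairs:
            entries += [
                ManifestEntry(
                    f"run{i:02d}r", base_seed + i, variant, n_laps,
                    {**overrides, "_reversed": True},
                )
                for i in range(n_runs)
            ]
        return cls(entries=entries)


def run_experiment(
    manifest: ExperimentManifest,
    out_dir: str | Path | None = None,
) -> tuple[list[SessionResult], dict]:
    """Execute every manifest entry; failures are logged, the rest continue.

    Returns the per-run session results and the pooled summary.  When
    ``out_dir`` is given, per-run CSV tables and a pooled summary JSON are
    written beneath it.
    """
    results: list[SessionResult] = []
    root = Path(out_dir) if out_dir is not None else None
    for entry in manifest.entries:
        cfg = entry.build_config(manifest.base_config)
        try:
            trajectory = None
            if entry.overrides.get("_reversed"):
                # reversed twin: same trajectory stream as the forward run
                from .trajectory import generate_track_trajectory

                _, ss_traj, _, _ = np.random.SeedSequence(entry.seed).spawn(4)
                trajectory = generate_track_trajectory(
                    cfg, entry.n_laps, np.random.default_rng(ss_traj)
                ).reversed()
            res = run_full_session(
                cfg, n_laps=entry.n_laps, seed=entry.seed, sim_id=entry.run_id,
                trajectory=trajectory,
            )
            results.append(res)
            if root is not None:
                _write_run(root / entry.run_id, res)
        except Exception:  # keep the remaining runs alive
            log.exception("run %s failed", entry.run_id)
    summary = pool_sessions(results)
    if root is not None:
        root.mkdir(parents=True, exist_ok=True)
        pooled = root / "pooled"
        pooled.mkdir(exist_ok=True)
        with open(pooled / "summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2)
    return results, summary


def _write_run(run_dir: Path, res: SessionResult) -> None:
    run_dir.mkdir(parents=True, exist_ok=True)
    res.trajectory.to_csv(run_dir / "trajectory.csv")
    for sid, s in res.sets.items():
        if s.fields is not None:
            s.fields.to_frame().to_csv(run_dir / f"fields_{sid}.csv", index=False)
        if s.phase_table is not None:
            s.phase_table.to_csv(run_dir / f"phase_stats_{sid}.csv", index=False)
    ev = events_frame(res.all_replays())
    ev.to_csv(run_dir / "replays.csv", index=False)


def pool_sessions(results: list[SessionResult]) -> dict:
    """Population summary across replicate sessions (both recording sets)."""
    run_speeds = [r.mean_run_speed for r in results]
    theta_speeds = [v for r in results for v in r.theta_speeds().values()
                    if np.isfinite(v)]
    corr_means, phase_tables, sample_tables = [], [], []
    for r in results:
        for s in r.sets.values():
            if s.phase_table is not None and not s.phase_table.empty:
                corr_means.append(np.abs(s.phase_table["corr"].to_numpy()))
                phase_tables.append(s.phase_table)
            if s.samples is not None and not s.samples.empty:
                tab = s.samples.copy()
                if s.phase_table is not None:
                    sub = s.phase_table.set_index(["neuron", "direction"]).subgroup
                    tab["subgroup"] = [
                        sub.get((n, d), "unclassified")
                        for n, d in zip(tab.neuron, tab.direction)
                    ]
                sample_tables.append(tab)
    events = {}
    for r in results:
        events.update(r.all_replays())
    replays = replay_speed_summary(events)

    summary: dict = {
        "n_sessions": len(results),
        "run_speed_mps": _ms(run_speeds),
        "theta_sequence_speed_mps": _ms(theta_speeds),
        "replay": replays,
    }
    if run_speeds and theta_speeds and np.mean(run_speeds) > 0:
        summary["sequence_speed_ratio"] = float(
            np.mean(theta_speeds) / np.mean(run_speeds)
        )
        if np.isfinite(replays.get("mean_speed_mps", np.nan)):
            summary["replay_speed_ratio"] = float(
                replays["mean_speed_mps"] / np.mean(run_speeds)
            )
    if corr_means:
        allc = np.concatenate(corr_means)
        summary["abs_corr"] = {"mean": float(allc.mean()), "sd": float(allc.std())}
    if phase_tables:
        pt = pd.concat(phase_tables, ignore_index=True)
        summary["subgroup_counts"] = pt.subgroup.value_counts().to_dict()
        good = pt[pt.fit_score >= 0.4]
        # slopes are fitted against field progress; in track-position
        # coordinates the leftward-lap slope changes sign, so precession
        # (phase falling with progress) appears as negative slopes on
        # rightward laps and positive slopes on leftward laps
        for d, lbl in ((1, "rightward"), (-1, "leftward")):
            grp = good[good.direction == d]
            if len(grp):
                pos_slope = grp.slope * d
                summary[f"frac_negative_slope_{lbl}"] = float((pos_slope < 0).mean())
    if sample_tables:
        pooled = pd.concat(sample_tables, ignore_index=True)
        prec = pooled[pooled.subgroup == "precessing"]
        lock = pooled[pooled.subgroup == "locking"]
        if len(prec) >= 50:
            centers, ridge = density_ridge(prec)
            summary["precessing_ridge"] = {
                "progress": centers.tolist(), "phase_deg": ridge.tolist(),
            }
            # drop of the density-ridge phase from field entry to 50% progress
            # (positive = phase decreases, i.e. precession)
            early = ridge[centers <= 15.0]
            mid = ridge[np.abs(centers - 50.0) <= 10.0]
            if early.size and mid.size:
                summary["precessing_entry_phase_deg"] = float(early[0])
                summary["precession_drop_deg"] = float(early[0] - mid.mean())
        if len(lock) >= 50:
            summary["locking_mode_deg"] = circular_mode(lock.phase_deg.to_numpy())
    return summary


def _ms(values) -> dict:
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return {"mean": np.nan, "sd": np.nan, "n": 0}
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "n": int(arr.size),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
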