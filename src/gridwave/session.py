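"""End-to-end track sessions: simulate, record, and analyze.

A "session" is one simulated animal running laps on a linear track with
idle periods at the ends.  Two interleaved recording sets (A and B) are
selected per network; each set is analyzed independently — field maps,
phase statistics, run-segment decoding with theta-quadruplet averaging, and
idle-period replay detection — mirroring how multiunit recordings would be
treated as separate experimental sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BehavioralState, SimulationConfig
from .decoding import (
    ThetaSequenceSummary,
    average_theta_quadruplets,
    decode_record,
)
from .phase import per_neuron_phase_stats, phase_samples
from .recording import (
    FiringFields,
    RecordingSet,
    ThetaCycles,
    compute_rate_maps,
    label_theta,
    merge_indices,
    recording_index,
    select_recording_regions,
    select_stable_neurons,
    spike_table,
)
from .replay import ReplayEvent, detect_replays
from .simulator import SpikeRecord, run_session, setup_phase
from .trajectory import Trajectory, generate_track_trajectory

__all__ = ["SessionResult", "SetAnalysis", "run_full_session", "analyze_record"]


@dataclass
class SetAnalysis:
    """All analyses for one recording set of one session."""

    set_id: str
    recording: RecordingSet
    fields: FiringFields | None = None
    phase_table: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None
    sequences: ThetaSequenceSummary | None = None
    replays: list[ReplayEvent] = field(default_factory=list)

    @property
    def usable(self) -> bool:
        return self.recording.usable and self.fields is not None

    @property
    def theta_speed_mps(self) -> float:
        return self.sequences.speed_mps if self.sequences else np.nan

    def mean_abs_corr(self) -> float:
        if self.phase_table is None or self.phase_table.empty:
            return np.nan
        return float(np.abs(self.phase_table["corr"].to_numpy()).mean())


@dataclass
class SessionResult:
    """One simulated session with its spike record and per-set analyses."""

    config: SimulationConfig
    trajectory: Trajectory
    record: SpikeRecord
    cycles: ThetaCycles
    sets: dict[str, SetAnalysis]
    allo_maps: dict[int, np.ndarray]
    sim_id: str = ""

    @property
    def mean_run_speed(self) -> float:
        return self.trajectory.mean_run_speed()

    def theta_speeds(self) -> dict[str, float]:
        return {sid: s.theta_speed_mps for sid, s in self.sets.items() if s.usable}

    def all_replays(self) -> dict[str, list[ReplayEvent]]:
        return {f"{self.sim_id}/{sid}": s.replays for sid, s in self.sets.items()}


def run_full_session(
    config: SimulationConfig,
    n_laps: int = 8,
    seed: int | np.random.SeedSequence = 0,
    sim_id: str = "",
    trajectory: Trajectory | None = None,
    record_radius: float | None = None,
    region_radius: float = 12.0,
) -> SessionResult:
    """Simulate one track session and run the full analysis pipeline.

    Randomness splits into independent streams for the allocentric setup,
    the trajectory, the network, and the recording-region placement, all
    derived from ``seed``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_setup, ss_traj, ss_net, ss_reg = ss.spawn(4)

    allo_maps = setup_phase(config, ss_setup) if config.allocentric_enabled else {}
    if trajectory is None:
        trajectory = generate_track_trajectory(
            config, n_laps, np.random.default_rng(ss_traj)
        )
    regions = {
        sid: select_recording_regions(
            config, np.random.default_rng(ss_reg.entropy % (2 ** 31)), sid,
            radius=record_radius, region_radius=region_radius,
        )
        for sid in ("A", "B")
    }
    rec_index = merge_indices(
        *[recording_index(config, r) for r in regions.values()]
    )
    record = run_session(
        config, trajectory, seed=ss_net, allo_maps=allo_maps,
        record_index=rec_index,
    )
    return analyze_record(
        config, trajectory, record, regions, allo_maps, sim_id=sim_id
    )


def analyze_record(
    config: SimulationConfig,
    trajectory: Trajectory,
    record: SpikeRecord,
    regions: dict[str, RecordingSet],
    allo_maps: dict[int, np.ndarray] | None = None,
    sim_id: str = "",
) -> SessionResult:
    """Run the per-set analysis pipeline on an existing spike record."""
    cycles = label_theta(
        record.drive_trace, config.dt,
        segment_mask=trajectory.run_mask(), f_theta=config.f_theta,
    )
    table = spike_table(record, trajectory)
    sets: dict[str, SetAnalysis] = {}
    for sid, reg in regions.items():
        out = SetAnalysis(set_id=sid, recording=reg)
        sets[sid] = out
        stable = select_stable_neurons(record, trajectory, reg, config)
        out.recording = stable
        if not stable.usable:
            continue
        fields = compute_rate_maps(record, trajectory, stable.neurons)
        out.fields = fields

        from .recording import _keys_of  # local to keep the namespace tidy

        keys = set(int(k) for k in _keys_of(stable.neurons))
        sub = table[table.key.map(lambda k: int(k) in keys)]
        samples = phase_samples(sub, fields, cycles)
        out.samples = samples
        if not samples.empty:
            out.phase_table = per_neuron_phase_stats(samples)

        run_decoded = decode_record(record, trajectory, fields, BehavioralState.RUN)
        out.sequences = average_theta_quadruplets(run_decoded, cycles, trajectory)

        # idle periods are decoded at finer resolution: wavefronts cross the
        # recorded regions within tens of ms
        idle_decoded = decode_record(
            record, trajectory, fields, BehavioralState.IDLE, bin_ms=10.0
        )
        out.replays = detect_replays(
            idle_decoded, trajectory.track_length_cm, sim_id=f"{sim_id}/{sid}"
        )
    return SessionResult(
        config=config, trajectory=trajectory, record=record,
        cycles=cycles, sets=sets, allo_maps=allo_maps or {}, sim_id=sim_id,
    )
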