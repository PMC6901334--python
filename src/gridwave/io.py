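"""HDF5 persistence for spike records and trajectory/kernel exports."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .config import SimulationConfig
from .simulator import SpikeRecord
from .trajectory import Trajectory

__all__ = ["load_record", "save_average_bump", "save_kernels", "save_record"]


def save_average_bump(path: str, bump) -> None:
    """Write an AverageBump (phase x offset grids and peak trace) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("phase_centers_deg", data=bump.phase_centers_deg)
        f.create_dataset("offsets", data=bump.offsets)
        f.create_dataset("activity", data=bump.activity, compression="gzip")
        f.create_dataset("axis_profile", data=bump.axis_profile)
        f.create_dataset("peak_trace", data=bump.peak_trace)
        f.attrs["motion_axis"] = bump.motion_axis


def save_record(path: str, record: SpikeRecord) -> None:
    """Write a SpikeRecord (events, drive trace, trajectory, config) to HDF5."""
    with h5py.File(path, "w") as f:
        ev = f.create_group("events")
        ev.create_dataset("pop", data=record.pop, compression="gzip")
        ev.create_dataset("y", data=record.y, compression="gzip")
        ev.create_dataset("x", data=record.x, compression="gzip")
        ev.create_dataset("step", data=record.step, compression="gzip")
        f.create_dataset("drive_trace", data=record.drive_trace, compression="gzip")
        f.attrs["dt"] = record.dt
        if record.snapshots is not None:
            f.create_dataset("snapshots", data=record.snapshots, compression="gzip")
            f.create_dataset("snapshot_steps", data=record.snapshot_steps)
            f.attrs["snapshot_origin"] = record.snapshot_origin
        if record.trajectory is not None:
            tr = f.create_group("trajectory")
            t = record.trajectory
            for name in ("pos", "vel", "state", "lap_index", "direction", "psi0"):
                tr.create_dataset(name, data=getattr(t, name), compression="gzip")
            tr.attrs["dt"] = t.dt
            tr.attrs["track_length_cm"] = t.track_length_cm
            tr.attrs["is_1d"] = t.is_1d
        if record.config is not None:
            f.attrs["config_json"] = json.dumps(record.config.to_dict())


def load_record(path: str) -> SpikeRecord:
    with h5py.File(path, "r") as f:
        trajectory = None
        if "trajectory" in f:
            tr = f["trajectory"]
            trajectory = Trajectory(
                dt=float(tr.attrs["dt"]),
                pos=tr["pos"][...],
                vel=tr["vel"][...],
                state=tr["state"][...],
                lap_index=tr["lap_index"][...],
                direction=tr["direction"][...],
                track_length_cm=float(tr.attrs["track_length_cm"]),
                is_1d=bool(tr.attrs["is_1d"]),
                psi0=tr["psi0"][...],
            )
        config = None
        if "config_json" in f.attrs:
            config = SimulationConfig.from_dict(json.loads(f.attrs["config_json"]))
        return SpikeRecord(
            dt=float(f.attrs["dt"]),
            pop=f["events/pop"][...],
            y=f["events/y"][...],
            x=f["events/x"][...],
            step=f["events/step"][...],
            drive_trace=f["drive_trace"][...],
            snapshots=f["snapshots"][...] if "snapshots" in f else None,
            snapshot_steps=f["snapshot_steps"][...] if "snapshot_steps" in f else None,
            snapshot_origin=tuple(f.attrs.get("snapshot_origin", (0, 0))),
            trajectory=trajectory,
            config=config,
        )


def save_kernels(path: str, config: SimulationConfig) -> None:
    """Export connectivity stencils and drive maps for inspection."""
    from .kernels import build_kernels, excitatory_drive_field

    k = build_kernels(config)
    with h5py.File(path, "w") as f:
        g = f.create_group("kernels")
        for pop, stencil in k.w_exc_out.items():
            g.create_dataset(f"exc_{pop}", data=stencil)
        g.create_dataset("inh", data=k.w_inh_out)
        d = f.create_group("drive")
        for state in ("run", "idle"):
            d.create_dataset(state, data=excitatory_drive_field(config, state))
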