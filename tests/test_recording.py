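import numpy as np
import pytest

from conftest import make_record, make_track_trajectory
from gridwave.config import SimulationConfig
from gridwave.recording import (
    compute_rate_maps,
    label_theta,
    rate_map_autocorrelation,
    select_recording_regions,
    select_stable_neurons,
    theta_mua,
)


class TestRecordingRegions:
    def test_ring_geometry(self, default_config):
        regions = select_recording_regions(default_config, seed=3, set_id="A")
        ctr = (default_config.n - 1) / 2.0
        d = np.linalg.norm(regions.centers - ctr, axis=1)
        assert np.allclose(d, 95.0, atol=0.5)
        ang = np.sort(np.arctan2(*(regions.centers - ctr).T) % (2 * np.pi))
        gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
        assert np.allclose(gaps, np.pi / 2, atol=1e-6)

    def test_set_b_offset_45_degrees(self, default_config):
        a = select_recording_regions(default_config, seed=3, set_id="A")
        b = select_recording_regions(default_config, seed=3, set_id="B")
        ctr = (default_config.n - 1) / 2.0
        ang_a = np.sort(np.arctan2(*(a.centers - ctr).T) % (2 * np.pi))
        ang_b = np.sort(np.arctan2(*(b.centers - ctr).T) % (2 * np.pi))
        rel = (ang_b - ang_a) % (np.pi / 2)
        assert np.allclose(rel, np.pi / 4, atol=1e-6)

    def test_oversized_ring_rejected(self, default_config):
        with pytest.raises(ValueError):
            select_recording_regions(default_config, radius=130.0)


class TestRateMaps:
    def _uniform_record(self, rate_hz=20.0, seed=0):
        traj = make_track_trajectory(n_laps=2)
        rng = np.random.default_rng(seed)
        run_steps = np.nonzero(traj.run_mask())[0]
        fire = run_steps[rng.random(len(run_steps)) < rate_hz / 1000.0]
        n = len(fire)
        return traj, make_record(np.zeros(n), np.full(n, 10), np.full(n, 10), fire, traj)

    def test_uniform_firing_gives_flat_map(self):
        traj, rec = self._uniform_record()
        ff = compute_rate_maps(rec, traj, np.array([[0, 10, 10]]))
        inner = ff.rate[0][3:-3]
        assert inner.std() / inner.mean() < 0.35
        assert inner.mean() == pytest.approx(20.0, rel=0.25)

    def test_localized_firing_gives_single_field(self):
        traj = make_track_trajectory(n_laps=2)
        run_steps = np.nonzero(traj.run_mask())[0]
        infield = run_steps[(traj.pos[run_steps] >= 40) & (traj.pos[run_steps] <= 60)]
        fire = infield[::4]
        n = len(fire)
        rec = make_record(np.zeros(n), np.full(n, 5), np.full(n, 5), fire, traj)
        ff = compute_rate_maps(rec, traj, np.array([[0, 5, 5]]))
        assert len(ff.fields[0]) == 1
        lo, hi = ff.fields[0][0]
        assert lo == pytest.approx(40, abs=8)
        assert hi == pytest.approx(60, abs=8)

    def test_occupancy_weighted_mean_rate_is_conserved(self):
        traj, rec = self._uniform_record(rate_hz=15.0, seed=3)
        ff = compute_rate_maps(rec, traj, np.array([[0, 10, 10]]))
        run_time_s = traj.run_mask().sum() * traj.dt / 1000.0
        mean_rate = (ff.rate[0] * ff.occupancy_s).sum() / ff.occupancy_s.sum()
        assert mean_rate == pytest.approx(rec.n_events / run_time_s, rel=0.05)


class TestStableSelection:
    def test_reliable_neuron_kept_silent_and_erratic_dropped(self, default_config):
        traj = make_track_trajectory(n_laps=4)
        regions = select_recording_regions(default_config, seed=0, set_id="A")
        cy, cx = regions.centers[0]
        stable_yx = (int(cy), int(cx))
        erratic_yx = (int(cy) + 1, int(cx))
        rng = np.random.default_rng(0)
        pops, ys, xs, steps = [], [], [], []
        run_steps = np.nonzero(traj.run_mask())[0]
        pos = traj.pos
        for lap in range(4):
            lap_steps = run_steps[traj.lap_index[run_steps] == lap]
            near = lap_steps[np.abs(pos[lap_steps] - 50.0) < 6.0]
            for s in near[::3]:  # stable field at 50 cm on every lap
                pops.append(0); ys.append(stable_yx[0]); xs.append(stable_yx[1]); steps.append(s)
            # spatially unselective neuron: fires all along the track
            for s in lap_steps[rng.random(len(lap_steps)) < 0.04]:
                pops.append(1); ys.append(erratic_yx[0]); xs.append(erratic_yx[1]); steps.append(s)
        rec = make_record(np.array(pops), np.array(ys), np.array(xs), np.array(steps), traj)
        out = select_stable_neurons(rec, traj, regions, default_config)
        kept = {tuple(n) for n in out.neurons}
        assert (0, *stable_yx) in kept
        assert (1, *erratic_yx) not in kept
        assert not out.usable  # fewer than 10 stable neurons overall


class TestAutocorrelation:
    def test_zero_lag_is_one(self):
        rng = np.random.default_rng(0)
        ac = rate_map_autocorrelation(rng.random((40, 40)))
        assert ac[20, 20] == pytest.approx(1.0)

    def test_hexagonal_lattice_has_six_inner_peaks(self):
        from scipy import ndimage
        n, spacing = 120, 24
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        basis = [(spacing, 0.0), (spacing / 2, spacing * np.sqrt(3) / 2)]
        field = np.zeros((n, n))
        for i in range(-8, 9):
            for j in range(-8, 9):
                cy = n / 2 + i * basis[0][1] + j * basis[1][1]
                cx = n / 2 + i * basis[0][0] + j * basis[1][0]
                field += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 3.0 ** 2))
        ac = rate_map_autocorrelation(field)
        mx = ndimage.maximum_filter(ac, 9)
        peaks = np.argwhere((ac == mx) & (ac > 0.2))
        ctr = np.array(ac.shape) // 2
        d = np.linalg.norm(peaks - ctr, axis=1)
        inner = np.sort(d[d > 1])[:6]
        assert len(inner) == 6
        assert inner.std() / inner.mean() < 0.1
        # peaks at 60-degree spacing
        ang = np.sort([np.arctan2(*(p - ctr)) % (2 * np.pi)
                       for p, dd in zip(peaks, d) if 1 < dd <= inner.max() + 1])[:6]
        gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
        assert np.allclose(gaps, np.pi / 3, atol=0.2)


class TestThetaLabeling:
    def test_trough_boundaries_every_125_ms(self):
        t = np.arange(4000)
        drive = 0.72 - 0.2 * np.cos(2 * np.pi * 8.0 * t / 1000.0)
        cycles = label_theta(drive, dt=1.0)
        gaps = np.diff(cycles.trough_steps)
        assert np.allclose(gaps, 125, atol=1)

    def test_phase_is_180_at_drive_maximum(self):
        t = np.arange(2000)
        drive = 0.72 - 0.2 * np.cos(2 * np.pi * 8.0 * t / 1000.0)
        cycles = label_theta(drive, dt=1.0)
        peak_steps = np.nonzero(np.isclose(drive, drive.max(), atol=1e-9))[0]
        mid = [s for s in peak_steps if cycles.cycle_of_step[s] >= 0]
        assert np.allclose(cycles.phase_deg[mid], 180.0, atol=4.0)

    def test_psi0_translates_boundaries(self):
        t = np.arange(4000)
        psi0 = np.pi / 2
        drive = 0.72 - 0.2 * np.cos(2 * np.pi * 8.0 * t / 1000.0 + psi0)
        cycles = label_theta(drive, dt=1.0)
        base = label_theta(0.72 - 0.2 * np.cos(2 * np.pi * 8.0 * t / 1000.0), dt=1.0)
        shift = (base.trough_steps[0] - cycles.trough_steps[0]) % 125
        expected = (psi0 / (2 * np.pi * 8.0) * 1000.0) % 125
        assert shift == pytest.approx(expected, abs=1.5)

    def test_constant_drive_yields_no_cycles(self):
        cycles = label_theta(np.full(1000, 0.72), dt=1.0)
        assert cycles.n_cycles == 0


class TestThetaMUA:
    def test_uniform_spiking_gives_flat_profile_and_linear_scaling(self):
        traj = make_track_trajectory(n_laps=2)
        rng = np.random.default_rng(1)
        run_steps = np.nonzero(traj.run_mask())[0]
        fire = run_steps[rng.random(len(run_steps)) < 0.3]
        rec1 = make_record(np.zeros(len(fire)), np.zeros(len(fire)),
                           np.zeros(len(fire)), fire, traj)
        cycles = label_theta(rec1.drive_trace, dt=1.0, segment_mask=traj.run_mask())
        _, mua1 = theta_mua(rec1, cycles)
        assert mua1.std() / mua1.mean() < 0.15
        double = np.concatenate([fire, fire])
        rec2 = make_record(np.zeros(len(double)), np.zeros(len(double)),
                           np.zeros(len(double)), double, traj)
        _, mua2 = theta_mua(rec2, cycles)
        assert np.allclose(mua2, 2 * mua1)
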