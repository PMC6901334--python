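import numpy as np
import pandas as pd
import pytest

from gridwave.phase import (
    SLOPE_BOUND,
    circular_linear_correlation,
    circular_linear_regression,
    circular_mode,
    classify_phase_behavior,
    density_ridge,
    directionality_and_speed_stratification,
    per_neuron_phase_stats,
    spike_density_map,
)


def brute_force_slope(phases_deg, x, bound=SLOPE_BOUND, step=0.01):
    """Independent oracle: exhaustive resultant-length maximization."""
    grid = np.arange(-bound, bound + step, step)
    phr = np.deg2rad(phases_deg)
    best, best_r = 0.0, -1.0
    for a in grid:
        r = abs(np.exp(1j * (phr - np.deg2rad(a) * x)).mean())
        if r > best_r:
            best, best_r = a, r
    return best, best_r


class TestCircularLinearRegression:
    def test_noiseless_precession_recovered_exactly(self):
        x = np.linspace(0, 100, 40)
        phases = (360.0 - 1.2 * x) % 360.0
        slope, offset, score = circular_linear_regression(phases, x)
        assert slope == pytest.approx(-1.2, abs=1e-3)
        assert score == pytest.approx(1.0, abs=1e-6)
        assert offset % 360.0 == pytest.approx(360.0, abs=0.5) or offset < 0.5

    def test_constant_phase_is_perfect_zero_slope_fit(self):
        x = np.linspace(0, 100, 30)
        slope, _, score = circular_linear_regression(np.full(30, 200.0), x)
        assert abs(slope) < 1e-3
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_uniform_random_phases_have_low_fit_score(self):
        rng = np.random.default_rng(12)
        phases = rng.uniform(0, 360, 500)
        x = rng.uniform(0, 100, 500)
        _, _, score = circular_linear_regression(phases, x)
        assert score < 0.15

    def test_matches_brute_force_grid_search_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(8, 60)
            true_slope = rng.uniform(-3.0, 3.0)
            x = rng.uniform(0, 100, n)
            phases = (true_slope * x + rng.normal(0, 40, n)) % 360.0
            slope, _, _ = circular_linear_regression(phases, x)
            oracle, _ = brute_force_slope(phases, x)
            assert slope == pytest.approx(oracle, abs=0.05)

    def test_invariant_to_full_cycle_phase_shift(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 100, 60)
        phases = (-1.0 * x + rng.normal(0, 30, 60)) % 360.0
        s1 = circular_linear_regression(phases, x)
        s2 = circular_linear_regression(phases + 360.0, x)
        assert s1[0] == pytest.approx(s2[0], abs=1e-6)
        assert s1[2] == pytest.approx(s2[2], abs=1e-9)

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValueError):
            circular_linear_regression(np.array([1.0, 2, 3, 4]), np.arange(4.0))


class TestCircularLinearCorrelation:
    def test_perfect_precession_has_unit_magnitude(self):
        x = np.linspace(0, 100, 50)
        phases = (360.0 - 1.5 * x) % 360.0
        assert abs(circular_linear_correlation(phases, x)) == pytest.approx(1.0, abs=1e-6)

    def test_independent_phases_have_near_zero_correlation(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 100, 2000)
        phases = rng.uniform(0, 360, 2000)
        assert abs(circular_linear_correlation(phases, x)) < 0.12

    def test_zero_positional_variance_is_an_error(self):
        with pytest.raises(ValueError):
            circular_linear_correlation(np.arange(10.0) * 10, np.full(10, 5.0))


class TestClassification:
    @pytest.mark.parametrize(
        "score, slope, expected",
        [
            (0.2, -2.0, "independent"),
            (0.8, -0.2, "locking"),      # range 20 deg
            (0.8, -1.5, "precessing"),   # range 150 deg
            (0.399, -3.0, "independent"),
            (0.401, -0.599, "locking"),  # range 59.9 deg
            (0.401, -0.601, "precessing"),
        ],
    )
    def test_cutoffs(self, score, slope, expected):
        assert classify_phase_behavior(score, slope) == expected


class TestDensityMaps:
    def test_uniform_input_gives_flat_map(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "progress": rng.uniform(0, 100, 20000),
            "phase_deg": rng.uniform(0, 360, 20000),
        })
        h, _, _ = spike_density_map(df)
        assert h.std() / h.mean() < 0.25

    def test_density_normalized(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "progress": rng.uniform(0, 100, 500),
            "phase_deg": rng.uniform(0, 360, 500),
        })
        h, _, _ = spike_density_map(df)
        assert h.sum() == pytest.approx(1.0)

    def test_ridge_tracks_synthetic_precession(self):
        rng = np.random.default_rng(2)
        prog = rng.uniform(0, 100, 6000)
        phase = (380.0 - 1.5 * prog + rng.normal(0, 25, 6000)) % 360.0
        df = pd.DataFrame({"progress": prog, "phase_deg": phase})
        centers, ridge = density_ridge(df)
        # ridge falls by ~1.5 deg per % progress
        fit = np.polyfit(centers, ridge, 1)[0]
        assert fit == pytest.approx(-1.5, abs=0.4)

    def test_circular_mode_near_trough(self):
        rng = np.random.default_rng(4)
        phases = (rng.vonmises(0.0, 4.0, 4000) * 180 / np.pi) % 360.0
        mode = circular_mode(phases)
        assert mode == pytest.approx(360.0, abs=15.0)


class TestStratification:
    def _samples(self, slope_by_dir, n_neurons=12, spikes=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for neuron in range(n_neurons):
            for d, slope in slope_by_dir.items():
                prog = rng.uniform(0, 100, spikes)
                ph = (360.0 + slope * prog + rng.normal(0, 30, spikes)) % 360.0
                rows.append(pd.DataFrame({
                    "neuron": neuron, "phase_deg": ph, "progress": prog,
                    "direction": d, "lap": rng.integers(0, 6, spikes),
                }))
        return pd.concat(rows, ignore_index=True)

    def test_mirroring_flips_slope_signs_exactly(self):
        samples = self._samples({1: -1.2})
        stats = per_neuron_phase_stats(samples)
        mirrored = samples.copy()
        mirrored["progress"] = 100.0 - mirrored["progress"]
        stats_m = per_neuron_phase_stats(mirrored)
        merged = stats.merge(stats_m, on=["neuron", "direction"], suffixes=("", "_m"))
        assert np.allclose(merged.slope, -merged.slope_m, atol=1e-3)

    def test_direction_summary_counts_negative_slopes(self):
        samples = self._samples({1: -1.2, -1: -1.2})
        stats = per_neuron_phase_stats(samples)
        out = directionality_and_speed_stratification(samples, stats)
        assert out["slope_sign_by_direction"][1]["frac_negative"] > 0.8

    def test_speed_effect_detected_with_high_power(self):
        # build sessions where faster laps carry steeper precession
        detected = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            rows = []
            lap_speed = {lap: 0.3 + 0.1 * (lap % 3) for lap in range(9)}
            for neuron in range(10):
                for lap, v in lap_speed.items():
                    prog = rng.uniform(0, 100, 15)
                    slope = -0.5 - 2.5 * (v - 0.3)
                    ph = (360.0 + slope * prog + rng.normal(0, 25, 15)) % 360.0
                    rows.append(pd.DataFrame({
                        "neuron": neuron, "phase_deg": ph, "progress": prog,
                        "direction": 1, "lap": lap,
                    }))
            samples = pd.concat(rows, ignore_index=True)
            stats = per_neuron_phase_stats(samples)
            out = directionality_and_speed_stratification(samples, stats, lap_speed)
            if out.get("kruskal_range", {}).get("p", 1.0) < 0.05:
                detected += 1
        assert detected >= 9  # power above 0.9 for a strong built-in effect
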