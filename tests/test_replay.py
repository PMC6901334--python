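import numpy as np
import pytest

from gridwave.decoding import DecodedTrajectory
from gridwave.replay import (
    ReplayEvent,
    detect_replays,
    direction_bias,
    fit_replay_line,
    label_direction,
    replay_speed_summary,
)

L = 100.0


def synthetic_idle_decode(
    events,
    total_ms=20000.0,
    hop=5.0,
    n_neurons=150,
    base_count=3.0,
    seed=0,
):
    """Idle decode with low baseline MUA and injected line-sweep events.

    ``events``: list of (t_start_ms, duration_ms, p0_cm, p1_cm).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(hop / 2, total_ms, hop)
    pos_bins = np.arange(1.0, L, 2.0)
    # outside events the decoder sits at the (stationary) animal position
    # with steady multiunit background, so chance fluctuations cannot
    # masquerade as trajectory sweeps
    ml = np.full(len(t), 50.0)
    counts = np.full((len(t), n_neurons), base_count / n_neurons)
    for t0, dur, p0, p1 in events:
        sel = (t >= t0) & (t < t0 + dur)
        frac = (t[sel] - t0) / dur
        ml[sel] = p0 + (p1 - p0) * frac
        counts[sel] += rng.poisson(30.0 / n_neurons, (sel.sum(), n_neurons))
    ml = np.clip(ml, pos_bins[0], pos_bins[-1])
    post = np.zeros((len(t), len(pos_bins)))
    idx = np.argmin(np.abs(ml[:, None] - pos_bins[None, :]), axis=1)
    post[np.arange(len(t)), idx] = 1.0
    return DecodedTrajectory(
        bin_centers_ms=t, pos_bins_cm=pos_bins, posterior=post,
        ml_pos_cm=pos_bins[idx], actual_pos_cm=np.zeros(len(t)), counts=counts,
    )


class TestDetection:
    def test_silent_idle_yields_no_events(self):
        dec = synthetic_idle_decode([])
        assert detect_replays(dec, L) == []

    def test_single_sweep_detected_with_correct_speed(self):
        dec = synthetic_idle_decode([(5000.0, 100.0, 0.0, 80.0)])
        events = detect_replays(dec, L)
        assert len(events) == 1
        assert events[0].speed_mps == pytest.approx(8.0, rel=0.15)

    def test_track_reflection_reflects_events(self):
        evs = [(4000.0, 100.0, 5.0, 85.0), (12000.0, 120.0, 90.0, 20.0)]
        dec = synthetic_idle_decode(evs)
        found = detect_replays(dec, L)
        mirrored = DecodedTrajectory(
            bin_centers_ms=dec.bin_centers_ms,
            pos_bins_cm=dec.pos_bins_cm,
            posterior=dec.posterior[:, ::-1],
            ml_pos_cm=L - dec.ml_pos_cm,
            actual_pos_cm=L - dec.actual_pos_cm,
            counts=dec.counts,
        )
        found_m = detect_replays(mirrored, L)
        assert len(found) == len(found_m) == 2
        for e, em in zip(found, found_m):
            assert em.speed_mps == pytest.approx(e.speed_mps, rel=1e-6)
            assert em.p_start_cm == pytest.approx(L - e.p_start_cm, abs=1e-6)

    def test_fit_recovers_speed_despite_alias_outliers(self):
        """Parameter recovery on line-plus-noise traces across 50 seeds."""
        failures = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            speed = rng.uniform(3.0, 12.0)       # m/s
            t = np.arange(0, 100, 5.0)
            p = 10.0 + speed / 10.0 * t + rng.normal(0, 2.0, len(t))
            # lattice-alias hops: a minority of bins jump by ~40 cm
            hop = rng.random(len(t)) < 0.2
            p[hop] += rng.choice([-39.0, 39.0], hop.sum())
            slope, _, r2, inliers = fit_replay_line(t, p)
            if abs(abs(slope) * 10.0 - speed) > 0.1 * speed:
                failures += 1
        assert failures <= 5  # within 10% in at least 90% of draws


class TestSummaries:
    def _event(self, speed, slope=None, p0=0.0, p1=80.0, animal=0.0):
        return ReplayEvent(
            t_start_ms=0.0, t_end_ms=100.0, speed_mps=speed,
            slope_mps=slope if slope is not None else speed,
            p_start_cm=p0, p_end_cm=p1, r2=0.9, animal_pos_cm=animal,
        )

    def test_single_event_statistics(self):
        out = replay_speed_summary({"sim0": [self._event(7.0)]})
        assert out["mean_speed_mps"] == pytest.approx(7.0)
        assert out["sd_speed_mps"] == 0.0
        assert out["counts"] == {"sim0": 1}

    def test_direction_labels(self):
        away = self._event(5.0, slope=+5.0, animal=0.0)
        toward = self._event(5.0, slope=-5.0, animal=0.0)
        assert label_direction(away, L) == "away"
        assert label_direction(toward, L) == "toward"
        # at the far end the signs invert
        away_far = self._event(5.0, slope=-5.0, animal=100.0)
        assert label_direction(away_far, L) == "away"

    def test_mirrored_event_sets_swap_counts(self):
        events = {
            f"s{i}": [self._event(5.0, slope=+5.0), self._event(5.0, slope=+5.0),
                      self._event(5.0, slope=-5.0)]
            for i in range(4)
        }
        out = direction_bias(events, L)
        mirrored = {
            sim: [self._event(e.speed_mps, slope=-e.slope_mps,
                              p0=L - e.p_start_cm, p1=L - e.p_end_cm,
                              animal=L - e.animal_pos_cm)
                  for e in evs]
            for sim, evs in events.items()
        }
        out_m = direction_bias(mirrored, L)
        assert out["n_away"] == out_m["n_away"]
        assert out["n_toward"] == out_m["n_toward"]

    def test_away_bias_detected_on_synthetic_ensemble(self):
        rng = np.random.default_rng(0)
        events = {}
        for i in range(10):
            evs = []
            for _ in range(rng.integers(6, 12)):
                out = rng.random() < 0.8
                evs.append(self._event(
                    6.0, slope=+6.0 if out else -6.0,
                    p0=5.0 if out else 80.0, p1=80.0 if out else 5.0,
                ))
            events[f"s{i}"] = evs
        out = direction_bias(events, L)
        assert out["n_away"] > out["n_toward"]
        assert out["mannwhitney_p"] < 0.05
        assert out["median_start_dist_cm"] < out["median_end_dist_cm"]
        assert out["wilcoxon_p"] < 0.05
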