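"""Replay direction bias in the low-velocity-gain network variant.

With the velocity gain halved, sheet locations map one-to-one onto track
positions, so replays — wavefronts nucleated at the attractor bumps that
encode the resting animal's position — propagate predominantly AWAY from
the animal.  This script demonstrates the statistics on synthetic events
(the full low-gain ensemble takes ~1 h; see gridwave.experiment for the
real thing with SimulationConfig().variant('low-gain')).
"""

import numpy as np

from gridwave.replay import ReplayEvent, direction_bias

rng = np.random.default_rng(0)
L = 100.0
events = {}
for i in range(12):
    evs = []
    for _ in range(rng.integers(5, 15)):
        at_left = rng.random() < 0.5
        animal = 0.0 if at_left else L
        outward = rng.random() < 0.75       # nucleation at the animal's bumps
        v = rng.normal(6.0, 1.5)
        sgn = (+1 if at_left else -1) * (+1 if outward else -1)
        p0 = animal + sgn * rng.uniform(0, 15) * (1 if outward else 5)
        p1 = p0 + sgn * v * 10.0
        evs.append(ReplayEvent(
            t_start_ms=0.0, t_end_ms=100.0, speed_mps=abs(v), slope_mps=sgn * v,
            p_start_cm=float(np.clip(p0, 0, L)), p_end_cm=float(np.clip(p1, 0, L)),
            r2=0.9, animal_pos_cm=animal,
        ))
    events[f"sim{i:02d}"] = evs

out = direction_bias(events, L)
print(f"events away from the animal: {out['n_away']}, toward: {out['n_toward']}")
print(f"Mann-Whitney U p (away > toward per simulation): {out['mannwhitney_p']:.2g}")
print(f"median start/end distance from the animal: "
      f"{out['median_start_dist_cm']:.0f} / {out['median_end_dist_cm']:.0f} cm "
      f"(Wilcoxon p {out.get('wilcoxon_p', float('nan')):.2g})")
print("replays start near the resting position and travel outward.")
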