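# gridwave

A spiking continuous-attractor network of grid cells, together with the
analysis pipeline that exposes its emergent temporal code: theta phase
precession, theta sequences, and replay.

## The science

Grid cells in the medial entorhinal cortex fire at the vertices of a
triangular spatial lattice. A well-supported mechanism is the continuous
attractor network: neurons on a 2D sheet with local excitation, surround
inhibition, and velocity-modulated drive form a lattice of activity bumps
that moves in register with the animal, so each neuron inherits grid-like
spatial tuning. `gridwave` implements this architecture with fully spiking
leaky integrate-and-fire neurons — five overlapping populations (four
excitatory, N/S/W/E, with output stencils displaced along their preferred
sheet directions; one inhibitory) on a 232 x 232 sheet:

    tau_m dphi/dt = -phi + sum_j w_j s_j(t - tau_s) + a (1 + alpha E_P . V) + zeta,

with spike threshold 1, reset to 0, and a hyperpolarization floor of -1.

The point of the spiking implementation is what happens at short
timescales when the external input changes with behavioral state:

- **Runs.** An 8 Hz theta oscillation of the inhibitory drive makes the
  attractor bumps oscillate in *size* (more inhibition, smaller bumps) and
  *speed* (more inhibition, faster bumps). Size oscillations produce
  single-neuron **theta phase precession**; speed oscillations produce
  population-level **theta sequences** — decoded position sweeps ahead of
  the animal within each cycle at roughly twice the running speed.
- **Quiescence.** Lowered, non-oscillating drive extinguishes bumps away
  from the sheet center and replaces them with traveling **wavefronts** of
  excitatory activity, which recorded populations decode as **replays**:
  rapid trajectory sweeps an order of magnitude faster than running.

The package contains the full model (configuration, kernels and drives,
fBm trajectories, the LIF core with synaptic delays, allocentric
drift-correction learning) and the full analysis chain (tetrode-like
recording emulation, rate maps and field stability, theta-cycle labeling,
circular-linear phase statistics with subgroup classification, Bayesian
population decoding with theta-quadruplet averaging, ripple-style replay
detection, bump segmentation/tracking, and two simplified conceptual
models of phase behavior). See `docs/methods.md` for the details and
numerical choices.

## A worked example

`examples/` holds one short narrative script per capability
(`kernels_and_drives.py`, `grid_lattice.py`, `track_session.py`,
`bump_oscillations.py`, `conceptual_models.py`, `replay_variants.py`).
The central one simulates and analyzes a complete track session:

```python
from gridwave import SimulationConfig, run_full_session
res = run_full_session(SimulationConfig(), n_laps=4, seed=7)
```

which prints (`python examples/track_session.py`, a few minutes):

```
mean running speed: 0.46 m/s
--- recording set A: 150 stable grid cells
    phase stats over 144 (neuron, direction) samples: mean |circular-linear corr| 0.31
    subgroups: {'precessing': 63, 'independent': 48, 'locking': 33}
    theta sequences: 41 cycle quadruplets, sweep speed 0.89 m/s (1.9x the animal)
    replays: 5 events, mean 7.0 m/s
--- recording set B: 150 stable grid cells
    phase stats over 133 (neuron, direction) samples: mean |circular-linear corr| 0.28
    subgroups: {'precessing': 51, 'independent': 50, 'locking': 32}
    theta sequences: 43 cycle quadruplets, sweep speed 0.83 m/s (1.8x the animal)
    replays: 7 events, mean 5.5 m/s
```

Reading: 150 excitatory neurons with lap-stable firing fields were
"recorded" from four sheet regions; their spike theta phases correlate
weakly with position (|r| ~ 0.2-0.3, a mixture of phase-independent,
phase-locking, and phase-precessing cells); averaging the Bayesian-decoded
position over quadruplets of theta cycles reveals within-cycle sweeps at
~0.9 m/s, about twice the running speed; and during the idle periods,
decoded wavefront events run several-fold faster still.

A thin CLI covers the simulation entry points
(`gridwave config | simulate | sweep`); everything else is library API
(`gridwave.session.run_full_session`, `gridwave.experiment.run_experiment`
for replicate ensembles and pooled summaries).

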