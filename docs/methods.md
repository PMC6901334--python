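# Methods

## The model

`gridwave` implements a spiking continuous-attractor network for a single
grid-cell module. Five populations of leaky integrate-and-fire neurons live
on an n x n sheet (default 232 x 232): four excitatory populations (N, S, W,
E) and one inhibitory population. A neuron's membrane potential phi follows
explicit-Euler leaky-integrator dynamics on a 1 ms grid,

    tau_m * dphi/dt = -phi + synaptic input + drive + noise,

with tau_m = 40 ms (excitatory) or 20 ms (inhibitory). When phi reaches the
threshold of 1 (arbitrary units) the neuron spikes and resets to 0;
potentials are floored at -1 as a hyperpolarization limit. Spikes reach
their targets after synaptic delays (exc->exc 5 ms, exc->inh 2 ms, inh->exc
2 ms) through translation-invariant kernels: a raised-cosine excitatory
kernel (peak 0.2, radius 6 neurons) whose output stencil is displaced 3
neurons along each excitatory population's preferred sheet direction, and
an inhibitory surround kernel (zero at the origin, trough -2.8 at radius
12, support radius 24) that targets excitatory neurons only. There are no
inhibitory-to-inhibitory connections.

Synaptic events enter the integrator right-hand side (each spike contributes
w * dt / tau_m to the postsynaptic potential per step). We verified the
alternative delta-synapse reading (phi jumps by w directly) destabilizes the
network into global synchronous firing at the default weights; the
integrated form produces the bump lattice and all phenomena below, so it is
the model's normative dynamics. An `instantaneous` mode remains available in
the configuration for comparison.

Excitatory drive is a radial field: supra-threshold (2.0 during runs, 1.6
during quiescence) at the sheet center, decaying as a raised cosine to a
sub-threshold floor of 0.8 toward the edges, which prevents boundary
artifacts on the nonperiodic sheet. Each excitatory population's drive is
multiplied by 1 + alpha * (E_P . V), alpha = 0.25 s/m, coupling running
velocity to the sheet and making the bump lattice path-integrate. The
inhibitory population receives a spatially uniform drive that oscillates at
the 8 Hz theta frequency during runs (0.72 +/- 0.2) and collapses to a
constant (0 during quiescence, 0.72 during allocentric pulses). Theta phase
0 is defined at troughs of this drive, where excitatory cells are most
disinhibited; multiunit activity of recorded cells indeed peaks at phase
0-15 degrees.

With random initial potentials the sheet self-organizes into a triangular
lattice of activity bumps (spacing ~35 neurons with the default kernels).
During quiescence the reduced drive extinguishes bumps outside the sheet
center and the outer region instead supports self-sustained traveling
wavefronts (normal propagation speed ~1.2 neurons/ms), nucleated at the
surviving bumps; these are the substrate of replay.

## Behavioral sessions

Sessions alternate end-to-end runs on a 100 cm linear track (default; the
length is a free parameter) with 3 s idle periods. Running speed follows a
fractional Brownian motion profile (Hurst 0.8, 10% relative amplitude,
floor 0.05 m/s) around a 0.5 m/s target; lap direction alternates. Between
each idle period and the next run, a 100 ms allocentric-correction pulse
replaces the excitatory drive field with a learned map for the current
track end, re-registering the bump lattice and cancelling path-integration
drift. The maps are learned in an accelerated setup phase before the
session: one run in each direction, each followed by a 1 s stationary
period at the end just reached during which excitatory spikes are tallied
per sheet location; tallies are linearly rescaled to the [0.8, 2.0] drive
range. We verified a 100 ms pulse fully re-registers a lattice displaced by
half a lattice period (residual < 0.2 neurons). An open-field mode
(Ornstein-Uhlenbeck velocity with reflective walls) exercises 2D path
integration.

Path integration is proportional to running speed within the behavioral
range: under run-state theta drive, lattice speed per unit running speed is
constant to within ~2% over 0.5-1.0 m/s (~71 neurons per meter of travel).
Outside that range the relation is nonlinear — superlinear below ~0.25 m/s
and saturating above ~1.5 m/s — a spiking-discreteness effect; linearity
checks therefore use the 0.5-1.0 m/s range.

## Recording and analyses

Recording emulates multiunit tetrodes: four circular regions (radius 12) at
distance 95 from the sheet center, equally spaced at a random common angle;
a second set is rotated 45 degrees, and each set is analyzed independently.
Up to 150 excitatory neurons per set are kept whose per-lap dominant-field
peak positions spread less than 10 cm, whose peak rate exceeds 1 spike/s,
and whose peak stands at least 2x above the map mean. Rate maps use 2 cm
bins, occupancy normalization over runs in both directions, and 4 cm
Gaussian smoothing; fields are contiguous stretches above 20% of the peak.

Phase statistics follow the circular-linear framework: the regression slope
maximizes the mean resultant length R(a) of phi_j - a x_j over a bounded
range, the fit score is R at the optimum, and the correlation is the
circular-circular correlation between measured phases and the fitted
predictor. The slope search is bounded to one theta cycle per field (3.6
deg per % of field progress): wider bounds lock onto a traveling-wave alias
— within a single pass, phase advances a full cycle for every ~6 cm of
travel, a ramp of ~0.58 x field-width(cm) deg/% that dominates the
resultant at wider bounds and even inverts the apparent slope sign.
Neurons with fewer than 5 in-field spikes are excluded; fit score < 0.4
classifies phase-independent cells, and a precession range (|slope| x
field size) of 60 degrees splits the rest into locking vs precessing.

Bayesian decoding assumes independent Poisson spike counts and a uniform
prior, computed in log space. Run segments use 20 ms windows sliding by
5 ms; idle segments use 10 ms windows (wavefronts cross a recording region
in tens of ms). Theta sequences are exposed by averaging decoded densities
over quadruplets of consecutive cycles: quadruplets with more than 10% of
bins decoded within 10 cm of a track end are discarded, leftward laps are
mirrored, and each quadruplet is aligned to the animal's position at its
midpoint. The averaged decoded position uses a ridge-following windowed
mean (+/-20 cm window re-centered on the fitted linear trend, 4
iterations); a plain posterior mean is shrunk toward zero by diffuse
posterior mass and underestimates the trend by half. The theta-sequence
speed is the steepest ordinary-least-squares slope of this trace over a
sliding half-cycle (62.5 ms) window.

Replay detection mirrors ripple-style event detection: the recorded
population's multiunit rate (Gaussian-smoothed) must peak 2 s.d. above the
idle mean, with event boundaries extended to the mean crossing; events of
50-300 ms are kept when a robust line — Theil-Sen seeded, refit on inliers
within 12 cm — captures at least half the bins, spans at least 30% of the
track, and reaches R^2 >= 0.5 on its inliers. The inlier mechanism matters
because with the default velocity gain several track positions share a
sheet-lattice phase, so maximum-likelihood positions hop between parallel
branches offset by ~39 cm. The span threshold was set so that detected
event counts (tens per simulation) and durations (~50-150 ms) match the
phenomenon's reported scale; all thresholds are exposed parameters.

Bump analyses run dedicated constant-velocity simulations. Fixed-drive
sweeps hold the inhibitory drive at five levels spanning the theta range
(0.52-0.92) for 2 s each: diameters come from supra-threshold connected
components (30% of the smoothed maximum) of 30 ms spike-count frames —
10 ms frames carry too few spikes per bump for stable segmentation — and
lattice speed from sub-pixel cross-correlation of successive 50 ms frames,
with a linear fit to the cumulative displacement trace (chaining raw pair
estimates accumulates noise). Bump diameter falls and bump speed rises
linearly with drive; these two relations are the mechanistic core of phase
precession and theta sequences respectively. The phase-resolved average
bump is accumulated in each bump's constant-velocity reference frame
(bumps tracked by nearest-centroid matching on 30 ms frames; a linear
reference fitted per four-cycle window); its total activity peaks near
phase 0/360 and its axial peak lags the reference early in the cycle and
leads mid-cycle — the sawtooth that becomes the decoded theta sequence.

## Numerical choices

Noise (i.i.d. normal, s.d. 0.002 on the integrator right-hand side) is
drawn from a large pre-generated pool indexed by a counter-based hash of
the timestep; with this amplitude the pool recurrence (>60 steps apart) has
no measurable dynamical effect, and sessions remain exactly reproducible
from (configuration, seed). All other randomness flows through named
`numpy` SeedSequence streams (initial potentials, trajectories, per-lap
theta offsets, region placement). Convolutions use FFTs (zero-padded for
the nonperiodic sheet, circular for periodic boundaries) in float32; a
session step costs ~2.5 ms on one core. Degenerate inputs are defined:
zero-occupancy rate-map bins are interpolated, all-zero allocentric tallies
abort setup, decoding handles zero rates in log space, and constant drive
produces no theta cycles.

## Problem sizes

Reported statistics use scaled-down ensembles chosen to keep a full
reproduction within minutes on one core: three (tests: two) replicate
8-lap sessions of the full 232 x 232 x 5 network with both recording sets
analyzed per session, five-level fixed-drive sweeps of 2 s per level, and
ten trajectory realizations for generator statistics. Population statistics
(correlation magnitudes, subgroup densities, replay counts) are noticeably
noisier at this scale than they would be with tens of replicates and more
laps; per-neuron spike counts in particular (~10-15 per direction) inflate
circular-linear correlation magnitudes relative to long recordings.

## What the generator does and does not emulate

The synthetic behavioral trajectories capture speed variability
(long-range-correlated fBm fluctuations) and the run/idle/correction
structure of track sessions, but no acceleration limits, no head direction,
and no behavioral variability in idle durations. Passing tests therefore
show the network and analysis chain behave correctly under idealized,
statistically stationary behavior — not that the model fits any particular
animal's behavior.

## Known limitations

- The pooled spike density of the precessing subgroup does not reproduce a
  clean falling ridge at this ensemble scale: although most individual
  precessing neurons have negative phase-progress slopes in both run
  directions, their phase offsets scatter by ~110 degrees and the pooled
  mode jumps from ~345 degrees at field entry to 15-75 degrees (just after
  the trough, reflecting the integrate-and-fire lag after disinhibition)
  by mid-field. The ridge-drop statistic is computed faithfully
  (continuity-constrained modal ridge) and reported as measured.
- Velocity response is linear only within the behavioral speed range (see
  above); sessions with much faster trajectories would mis-integrate.
- A single grid module; no spike-frequency adaptation, gamma dynamics,
  Up/Down states, or cell-type (stellate/pyramidal, LII/LIII) distinctions.
- The replay detector fits a single line per event; split (two-field)
  decoded distributions are handled only through the inlier mechanism.
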