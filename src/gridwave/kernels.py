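"""Synaptic connectivity kernels and external drive fields.

Connectivity is translation-invariant on the neural sheet.  Excitatory
neurons excite all populations through a compact raised-cosine kernel whose
output stencil is displaced by ``xi_shift`` neurons along each population's
preferred sheet direction; inhibitory interneurons inhibit only excitatory
neurons through a surround (center-zero) kernel.  External drive is a radial
field for excitatory populations (supra-threshold at the sheet center,
decaying to a sub-threshold floor at the edges) and a spatially uniform,
optionally theta-modulated, scalar for the inhibitory population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import BehavioralState, SimulationConfig, resolve_params

__all__ = [
    "SHEET_DIRECTIONS",
    "ConnectivityKernels",
    "build_kernels",
    "excitatory_drive_field",
    "excitatory_kernel",
    "inhibitory_drive",
    "inhibitory_kernel",
    "learn_allocentric_drive",
]

# Preferred output-shift direction on the sheet for each excitatory
# population, as (dy, dx) in array coordinates with y increasing upward.
SHEET_DIRECTIONS: dict[str, tuple[int, int]] = {
    "N": (1, 0),    # up
    "S": (-1, 0),   # down
    "W": (0, -1),   # left
    "E": (0, 1),    # right
}

# Preferred spatial (allocentric) direction, as (Ex, Ey) unit vectors.
SPATIAL_DIRECTIONS: dict[str, tuple[float, float]] = {
    "N": (0.0, 1.0),
    "S": (0.0, -1.0),
    "W": (-1.0, 0.0),
    "E": (1.0, 0.0),
}

POPULATIONS = ("N", "S", "W", "E")


def excitatory_kernel(
    offset: np.ndarray | tuple[float, float] | float,
    w_mag: float = 0.2,
    r_w: float = 6.0,
) -> np.ndarray | float:
    """Excitatory synaptic weight at a sheet displacement.

    Raised cosine of radius ``r_w``: w(r) = w_mag (1 + cos(pi r / r_w)) / 2
    for r < r_w and zero beyond.  ``offset`` may be a scalar radius or a
    (dy, dx) displacement.
    """
    r = _radius(offset)
    w = np.where(r < r_w, w_mag * (1.0 + np.cos(np.pi * np.minimum(r, r_w) / r_w)) / 2.0, 0.0)
    return w if isinstance(w, np.ndarray) and w.ndim else float(w)


def inhibitory_kernel(
    offset: np.ndarray | tuple[float, float] | float,
    w_mag: float = 2.8,
    r_w: float = 12.0,
) -> np.ndarray | float:
    """Inhibitory (surround) weight: zero at the origin, trough -w_mag at r_w.

    w(r) = -w_mag (1 - cos(pi r / r_w)) / 2 for r < 2 r_w and zero beyond.
    """
    r = _radius(offset)
    w = np.where(r < 2.0 * r_w, -w_mag * (1.0 - np.cos(np.pi * np.minimum(r, 2.0 * r_w) / r_w)) / 2.0, 0.0)
    return w if isinstance(w, np.ndarray) and w.ndim else float(w)


def _radius(offset) -> np.ndarray | float:
    arr = np.asarray(offset, dtype=float)
    if arr.ndim == 0:
        return np.abs(arr)
    if arr.shape[-1] == 2:
        return np.sqrt(np.sum(arr ** 2, axis=-1))
    return np.abs(arr)


@dataclass
class ConnectivityKernels:
    """Dense 2D weight stencils, centered, odd side length.

    ``w_exc_out[P]`` is the excitatory kernel translated by ``xi_shift``
    along population P's sheet direction; ``w_inh_out`` targets excitatory
    neurons only (there are no inhibitory-to-inhibitory connections).
    """

    w_exc_out: dict[str, np.ndarray]
    w_inh_out: np.ndarray
    exc_half: int            # half-width of the excitatory stencils
    inh_half: int            # half-width of the inhibitory stencil

    def stencil_value(self, population: str, dy: float, dx: float) -> float:
        """Weight from a neuron of ``population`` at displacement (dy, dx)."""
        k = self.w_exc_out[population]
        i, j = int(round(dy)) + self.exc_half, int(round(dx)) + self.exc_half
        if 0 <= i < k.shape[0] and 0 <= j < k.shape[1]:
            return float(k[i, j])
        return 0.0


def build_kernels(config: SimulationConfig) -> ConnectivityKernels:
    """Build the four shifted excitatory stencils and the inhibitory stencil."""
    xi = config.xi_shift
    exc_half = int(np.ceil(config.r_w_exc + xi))
    inh_half = int(np.ceil(2.0 * config.r_w_inh)) - 1
    if config.r_w_exc + xi > config.n / 2 or inh_half >= config.n:
        raise ValueError("kernel support exceeds sheet size; increase n")

    ax_e = np.arange(-exc_half, exc_half + 1)
    w_exc: dict[str, np.ndarray] = {}
    for pop, (dy, dx) in SHEET_DIRECTIONS.items():
        # kernel centered at +xi * e_P: source output lands ahead of the neuron
        yy = ax_e[:, None] - xi * dy
        xx = ax_e[None, :] - xi * dx
        r = np.sqrt(yy ** 2 + xx ** 2)
        w_exc[pop] = np.asarray(excitatory_kernel(r, config.w_mag_exc, config.r_w_exc))

    ax_i = np.arange(-inh_half, inh_half + 1)
    r_i = np.sqrt(ax_i[:, None] ** 2 + ax_i[None, :] ** 2)
    w_inh = np.asarray(inhibitory_kernel(r_i, config.w_mag_inh, config.r_w_inh))
    return ConnectivityKernels(w_exc_out=w_exc, w_inh_out=w_inh,
                               exc_half=exc_half, inh_half=inh_half)


def sheet_radial_coordinate(n: int) -> np.ndarray:
    """Scaled radial distance rho from the sheet center.

    rho = 0 at the center ((n+1)/2, (n+1)/2 in 1-based coordinates) and
    approximately 1 at the midpoint of a sheet edge.
    """
    coords = np.arange(1, n + 1, dtype=float)
    cy = cx = (n + 1) / 2.0
    dist = np.sqrt((coords[:, None] - cy) ** 2 + (coords[None, :] - cx) ** 2)
    return dist / (n / 2.0)


def excitatory_drive_field(
    config: SimulationConfig, state: "BehavioralState | str"
) -> np.ndarray:
    """Per-neuron excitatory drive map for one behavioral state.

    Radial raised-cosine profile from a_max at the center down to a_min for
    rho >= rho_a; with ``uniform_drive`` the map is constant a_max.
    """
    p = resolve_params(config, state)
    if config.uniform_drive:
        return np.full((config.n, config.n), p.a_max_exc)
    rho = sheet_radial_coordinate(config.n)
    inside = rho < p.rho_a_exc
    prof = p.a_min_exc + (p.a_max_exc - p.a_min_exc) * (
        1.0 + np.cos(np.pi * np.minimum(rho, p.rho_a_exc) / p.rho_a_exc)
    ) / 2.0
    return np.where(inside, prof, p.a_min_exc)


def inhibitory_drive(
    t_ms: np.ndarray | float,
    psi0: float,
    config: SimulationConfig,
    state: "BehavioralState | str",
) -> np.ndarray | float:
    """Scalar inhibitory drive a_inh(t) = a_mag - a_theta cos(2 pi f t + psi0)."""
    p = resolve_params(config, state)
    t = np.asarray(t_ms, dtype=float) / 1000.0
    val = p.a_mag_inh - p.a_theta_inh * np.cos(2.0 * np.pi * p.f_theta * t + psi0)
    return val if np.ndim(t_ms) else float(val)


def learn_allocentric_drive(
    spike_tallies: np.ndarray,
    config: SimulationConfig,
    lo: float | None = None,
    hi: float | None = None,
) -> np.ndarray:
    """Rescale per-neuron spike tallies into an allocentric drive map.

    Tallies collected at one track end during the setup learning period are
    linearly mapped onto [a_min_exc, a_max_exc(allo)]; zero-tally neurons get
    the floor.  The map is invariant to overall tally scale.
    """
    tallies = np.asarray(spike_tallies, dtype=float)
    if tallies.max() <= 0:
        raise RuntimeError("allocentric setup failed: no spikes tallied")
    if lo is None:
        lo = config.a_min_exc
    if hi is None:
        hi = config.a_max_exc.get(BehavioralState.ALLOCENTRIC)
    span = tallies.max() - tallies.min()
    if span == 0:
        return np.full_like(tallies, hi)
    return lo + (hi - lo) * (tallies - tallies.min()) / span
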