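"""Model configuration and behavioral-state parameter resolution.

The network is parameterized by a single flat configuration object.  A few
drive parameters take different values depending on the animal's behavioral
state (running, idle/quiescent, or receiving a brief allocentric correction);
those are stored as per-state triples and resolved with :func:`resolve_params`.

All potentials, drives, and synaptic weights are in arbitrary units (a.u.),
with the spiking threshold fixed at 1.  Times are in milliseconds unless a
field name says otherwise; spatial sheet distances are in neuron units.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "BehavioralState",
    "ConfigError",
    "ResolvedParams",
    "SimulationConfig",
    "StateValue",
    "resolve_params",
]


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configurations."""


class BehavioralState(enum.IntEnum):
    """Behavioral state of the simulated animal.

    The integer codes are used in per-timestep state arrays.
    """

    RUN = 0
    IDLE = 1
    ALLOCENTRIC = 2

    @classmethod
    def from_label(cls, label: "BehavioralState | str") -> "BehavioralState":
        if isinstance(label, cls):
            return label
        try:
            return _STATE_ALIASES[str(label).strip().lower()]
        except KeyError:
            raise ConfigError(f"unknown behavioral state: {label!r}") from None


_STATE_ALIASES = {
    "run": BehavioralState.RUN,
    "runs": BehavioralState.RUN,
    "idle": BehavioralState.IDLE,
    "quiescent": BehavioralState.IDLE,
    "allo": BehavioralState.ALLOCENTRIC,
    "allocentric": BehavioralState.ALLOCENTRIC,
}


@dataclass(frozen=True)
class StateValue:
    """A parameter taking distinct values in the run / idle / allocentric states."""

    run: float
    idle: float
    allo: float

    def get(self, state: BehavioralState) -> float:
        if state == BehavioralState.RUN:
            return self.run
        if state == BehavioralState.IDLE:
            return self.idle
        return self.allo


@dataclass
class SimulationConfig:
    """All model, trajectory, and orchestration parameters.

    Defaults reproduce the standard parameter set: a 232x232 sheet of five
    overlapping populations, 1 ms timestep, 8 Hz theta drive to interneurons
    during runs, and reduced non-oscillating drive during quiescence.
    """

    # -- network geometry and integration
    n: int = 232                    # neurons per side, per population
    dt: float = 1.0                 # ms
    tau_m_exc: float = 40.0         # ms, excitatory membrane time constant
    tau_m_inh: float = 20.0         # ms, inhibitory membrane time constant
    tau_s_ee: float = 5.0           # ms, exc -> exc synaptic delay
    tau_s_ei: float = 2.0           # ms, exc -> inh synaptic delay
    tau_s_inh: float = 2.0          # ms, inh -> exc synaptic delay

    # -- drive (state-dependent entries as run/idle/allo triples)
    a_max_exc: StateValue = field(default_factory=lambda: StateValue(2.0, 1.6, 2.0))
    a_min_exc: float = 0.8
    rho_a_exc: StateValue = field(default_factory=lambda: StateValue(1.2, 0.9, 1.2))
    a_mag_inh: StateValue = field(default_factory=lambda: StateValue(0.72, 0.0, 0.72))
    a_theta_inh: StateValue = field(default_factory=lambda: StateValue(0.2, 0.0, 0.0))
    f_theta: float = 8.0            # Hz

    # -- connectivity
    w_mag_exc: float = 0.2
    r_w_exc: float = 6.0            # neurons; kernel support radius
    w_mag_inh: float = 2.8
    r_w_inh: float = 12.0           # neurons; inhibitory kernel trough radius
    xi_shift: float = 3.0           # neurons; directional output shift

    # -- synaptic integration
    # "instantaneous": a presynaptic spike adds its weight directly to the
    # postsynaptic potential after the delay (delta-synapse LIF);
    # "integrated": the weighted spike sum enters the leaky-integrator
    # right-hand side like the drive (contributing w * dt / tau_m per step).
    # The integrated form is the model's normative dynamics; the
    # instantaneous form destabilizes the network at the default weights.
    synapse_mode: str = "integrated"

    # -- velocity coupling and noise
    alpha_gain: float = 0.25        # s/m, velocity gain
    noise_var_exc: float = 0.002 ** 2
    noise_var_inh: float = 0.002 ** 2

    # -- boundary / variant flags
    boundary: str = "nonperiodic"   # {nonperiodic, periodic}
    uniform_drive: bool = False
    allocentric_enabled: bool = True

    # -- trajectory / behavioral schedule
    track_length_cm: float = 100.0
    run_speed_target: float = 0.5   # m/s
    fbm_hurst: float = 0.8
    fbm_rel_amp: float = 0.1        # speed fluctuation, fraction of target
    min_speed: float = 0.05         # m/s, clip floor for fBm speed
    idle_duration_s: float = 3.0
    allo_duration_s: float = 0.1
    track_angle_deg: float = 0.0    # track orientation in the 2D plane
    arena_side_cm: float = 180.0    # open-field arena side

    # -- setup / bookkeeping
    settle_duration_s: float = 1.0      # initial relaxation before behavior
    learning_duration_s: float = 1.0    # allocentric tally window per track end
    snapshot_interval_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # spec'd invariants: positivity, state tables, boundary/drive pairing
    def validate(self) -> None:
        positive = [
            "dt", "tau_m_exc", "tau_m_inh", "tau_s_ee", "tau_s_ei", "tau_s_inh",
            "f_theta", "w_mag_exc", "r_w_exc", "w_mag_inh", "r_w_inh",
            "a_min_exc", "track_length_cm", "run_speed_target",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.n < 2:
            raise ConfigError("n must be at least 2")
        if self.xi_shift < 0 or self.alpha_gain < 0:
            raise ConfigError("xi_shift and alpha_gain must be nonnegative")
        if self.noise_var_exc < 0 or self.noise_var_inh < 0:
            raise ConfigError("noise variances must be nonnegative")
        if self.synapse_mode not in ("instantaneous", "integrated"):
            raise ConfigError(f"unknown synapse_mode: {self.synapse_mode!r}")
        if self.boundary not in ("nonperiodic", "periodic"):
            raise ConfigError(f"unknown boundary mode: {self.boundary!r}")
        if self.boundary == "periodic" and not self.uniform_drive:
            raise ConfigError(
                "periodic boundary requires uniform_drive (set uniform_drive=True)"
            )
        for name in ("a_max_exc", "rho_a_exc", "a_mag_inh", "a_theta_inh"):
            sv = getattr(self, name)
            if not isinstance(sv, StateValue):
                raise ConfigError(f"{name} must be a StateValue triple")
        for state in BehavioralState:
            if self.a_max_exc.get(state) <= 0:
                raise ConfigError("a_max_exc must be strictly positive in all states")

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict[str, Any]:
        """Flatten to a plain key->value mapping (state triples get suffixes)."""
        out: dict[str, Any] = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, StateValue):
                out[f"{f.name}_run"] = value.run
                out[f"{f.name}_idle"] = value.idle
                out[f"{f.name}_allo"] = value.allo
            else:
                out[f.name] = value
        return out

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        """Build a config from a flat mapping.

        Missing keys take defaults; unknown keys are errors.
        """
        state_fields = {
            f.name for f in dataclasses.fields(cls)
            if isinstance(getattr(cls(), f.name), StateValue)
        }
        plain_fields = {f.name for f in dataclasses.fields(cls)} - state_fields
        kwargs: dict[str, Any] = {}
        triples: dict[str, dict[str, float]] = {}
        for key, value in data.items():
            if key in plain_fields:
                kwargs[key] = value
                continue
            base, _, suffix = key.rpartition("_")
            if base in state_fields and suffix in ("run", "idle", "allo"):
                triples.setdefault(base, {})[suffix] = float(value)
            else:
                raise ConfigError(f"unknown configuration key: {key!r}")
        defaults = cls()
        for base, parts in triples.items():
            ref: StateValue = getattr(defaults, base)
            kwargs[base] = StateValue(
                run=parts.get("run", ref.run),
                idle=parts.get("idle", ref.idle),
                allo=parts.get("allo", ref.allo),
            )
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration file must be a flat mapping")
        return cls.from_dict(data)

    def replace(self, **changes: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    # ---------------------------------------------------------- variants
    def variant(self, name: str) -> "SimulationConfig":
        """Named network variants used throughout the study."""
        if name == "default":
            return self.replace()
        if name == "low-gain":
            return self.replace(alpha_gain=self.alpha_gain / 2.0)
        if name == "periodic-uniform":
            return self.replace(boundary="periodic", uniform_drive=True)
        if name == "no-allocentric":
            return self.replace(allocentric_enabled=False)
        raise ConfigError(f"unknown variant: {name!r}")


@dataclass(frozen=True)
class ResolvedParams:
    """State-resolved scalar drive parameters, other fields passed through."""

    state: BehavioralState
    a_max_exc: float
    a_min_exc: float
    rho_a_exc: float
    a_mag_inh: float
    a_theta_inh: float
    f_theta: float


def resolve_params(
    config: SimulationConfig, state: "BehavioralState | str"
) -> ResolvedParams:
    """Resolve the state-dependent drive parameters for one behavioral state."""
    st = BehavioralState.from_label(state)
    return ResolvedParams(
        state=st,
        a_max_exc=config.a_max_exc.get(st),
        a_min_exc=config.a_min_exc,
        rho_a_exc=config.rho_a_exc.get(st),
        a_mag_inh=config.a_mag_inh.get(st),
        a_theta_inh=config.a_theta_inh.get(st),
        f_theta=config.f_theta,
    )
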