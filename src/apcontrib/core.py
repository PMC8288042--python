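"""Generic Hodgkin-Huxley mathematical core.

Gating kinetics, channel currents, reversal potentials and right-hand-side
assembly for conductance-based membrane models in which

* every gating variable ``x`` relaxes as ``dx/dt = (x_inf(u) - x) / tau_x(u)``
  toward a sigmoidal steady state ``x_inf(u) = 1 / (1 + exp(a1*u + a2))``
  with a time constant ``tau_x(u) = 1 / sum_i b_i * exp(c_i*u + d_i)``,
  where the driver ``u`` is usually the membrane voltage (a concentration
  for ligand-dependent gates such as Ca2+-dependent inactivation), and
* every gated current has the form
  ``I_Y = gbar_Y * prod_j x_j^p_j * (V - E_ion)`` in pA/pF.

Anything outside this algebra (inward-rectifier shaping, pumps, exchangers,
intracellular Ca2+ handling) enters through the ``extra_currents`` and
``non_gating_dynamics`` hooks of :class:`CellModel`.

Units: ms, mV, pF, nS/pF (so conductance * mV = pA/pF), mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "PhysicalConstants",
    "IonConcentrations",
    "CellModel",
    "ConfigurationError",
    "DomainError",
    "steady_state",
    "time_constant",
    "gate_derivative",
    "nernst",
    "channel_current",
    "StateView",
]

#: largest magnitude allowed inside exp(); stiff solvers probe extreme
#: voltages during Newton iterations and must never see inf/NaN
EXP_CLAMP = 500.0

ION_VALENCE = {"Na": 1, "K": 1, "Ca": 2, "Cl": -1}


class ConfigurationError(ValueError):
    """A model specification is internally inconsistent."""


class DomainError(ValueError):
    """A quantity left its physical domain (non-positive tau, concentration...)."""


def _safe_exp(z):
    return np.exp(np.clip(z, -EXP_CLAMP, EXP_CLAMP))


@dataclass(frozen=True)
class GateSpec:
    """One activation/inactivation variable.

    Parameters
    ----------
    name:
        State-variable name (e.g. ``n``, ``nf``, ``l``, ``Cai``).
    ss_a1, ss_a2:
        Sigmoid coefficients of the steady state, ``1/(1+exp(a1*u + a2))``.
        ``a1 < 0`` gives an activation gate (x_inf rises with the driver).
    tau_terms:
        Non-empty sequence of ``(b, c, d)`` triples; the relaxation rate is
        ``1/tau = sum b*exp(c*u + d)`` in 1/ms.
    driver:
        Name of the state variable that drives the kinetics; ``"V"`` for
        voltage gates, a concentration state for ligand gates.
    """

    name: str
    ss_a1: float
    ss_a2: float
    tau_terms: tuple[tuple[float, float, float], ...]
    driver: str = "V"

    def __post_init__(self):
        if len(self.tau_terms) == 0:
            raise ConfigurationError(f"gate {self.name!r}: tau_terms is empty")
        object.__setattr__(
            self, "tau_terms", tuple(tuple(float(v) for v in t) for t in self.tau_terms)
        )


def steady_state(gate: GateSpec, u):
    """Steady-state open fraction x_inf(u) = 1/(1+exp(a1*u + a2)).

    Overflow-safe: saturates to 0/1 for extreme arguments, never NaN.
    """
    return 1.0 / (1.0 + _safe_exp(gate.ss_a1 * np.asarray(u, dtype=float) + gate.ss_a2))


def time_constant(gate: GateSpec, u):
    """Relaxation time constant tau(u) = 1 / sum_i b_i exp(c_i u + d_i), in ms."""
    u = np.asarray(u, dtype=float)
    rate = np.zeros_like(u)
    for b, c, d in gate.tau_terms:
        rate = rate + b * _safe_exp(c * u + d)
    if np.any(rate <= 0.0):
        bad = np.atleast_1d(u)[np.atleast_1d(rate) <= 0.0]
        raise DomainError(
            f"gate {gate.name!r}: relaxation rate is non-positive at driver value "
            f"{bad.ravel()[0]:g} (tau would be infinite or negative)"
        )
    return 1.0 / rate


def gate_derivative(x, gate: GateSpec, u):
    """dx/dt = (x_inf(u) - x)/tau(u); zero exactly at the fixed point."""
    return (steady_state(gate, u) - x) / time_constant(gate, u)


@dataclass(frozen=True)
class PhysicalConstants:
    """F in C/mol, T in K, R in mJ/(mol K); R*T/F is then directly in mV."""

    F: float = 96487.0
    T: float = 310.15
    R: float = 8314.0

    def __post_init__(self):
        if self.F <= 0 or self.T <= 0 or self.R <= 0:
            raise DomainError("physical constants must be strictly positive")


def nernst(z: int, c_out: float, c_in: float, constants: PhysicalConstants) -> float:
    """Nernst reversal potential (R*T)/(z*F)*ln(c_out/c_in), in mV."""
    if c_out <= 0 or c_in <= 0:
        raise DomainError(
            f"nernst: concentrations must be positive (got out={c_out}, in={c_in})"
        )
    return constants.R * constants.T / (z * constants.F) * float(np.log(c_out / c_in))


@dataclass(frozen=True)
class IonConcentrations:
    """Extracellular concentrations (mM) and fixed intracellular fallbacks.

    An intracellular concentration listed in ``internal_states`` is read from
    the live state vector instead of ``internal``.
    """

    external: Mapping[str, float]
    internal: Mapping[str, float] = field(default_factory=dict)
    internal_states: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for tag, m in (("external", self.external), ("internal", self.internal)):
            for ion, c in m.items():
                if c <= 0:
                    raise DomainError(f"{tag} [{ion}] = {c} must be > 0")


@dataclass(frozen=True)
class ChannelSpec:
    """A gated ohmic current ``gbar * prod gate^power * (V - E)``.

    ``ion`` selects a Nernst reversal potential; alternatively ``e_fixed``
    pins E (mV). A channel with no gates is a linear background current.
    """

    name: str
    conductance: float
    gate_powers: tuple[tuple[str, int], ...] = ()
    ion: str | None = None
    e_fixed: float | None = None

    def __post_init__(self):
        if self.conductance < 0:
            raise ConfigurationError(f"channel {self.name!r}: conductance < 0")
        if (self.ion is None) == (self.e_fixed is None):
            raise ConfigurationError(
                f"channel {self.name!r}: exactly one of ion / e_fixed is required"
            )
        if self.ion is not None and self.ion not in ION_VALENCE:
            raise ConfigurationError(
                f"channel {self.name!r}: unknown ion {self.ion!r}"
            )
        for g, p in self.gate_powers:
            if int(p) != p or p < 0:
                raise ConfigurationError(
                    f"channel {self.name!r}: power of gate {g!r} must be a "
                    f"non-negative integer, got {p}"
                )
        object.__setattr__(
            self, "gate_powers", tuple((str(g), int(p)) for g, p in self.gate_powers)
        )


def channel_current(
    channel: ChannelSpec, gate_values: Mapping[str, float], V: float, E: float
) -> float:
    """Instantaneous current of one channel in pA/pF."""
    open_frac = 1.0
    for g, p in channel.gate_powers:
        if g not in gate_values:
            raise ConfigurationError(
                f"channel {channel.name!r} references gate {g!r} which is absent"
            )
        open_frac *= gate_values[g] ** p
    return channel.conductance * open_frac * (V - E)


class StateView:
    """Read-only name-indexed view into a raw state vector (cheap, no dict copy)."""

    __slots__ = ("_y", "_index")

    def __init__(self, y: np.ndarray, index: Mapping[str, int]):
        self._y = y
        self._index = index

    def __getitem__(self, name: str) -> float:
        return self._y[self._index[name]]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def as_dict(self) -> dict[str, float]:
        return {k: self._y[i] for k, i in self._index.items()}


class CellModel:
    """An assembled ODE system: membrane voltage + gates + extra dynamics.

    Parameters
    ----------
    gates, channels:
        The Hodgkin-Huxley part of the model.
    capacitance:
        Membrane capacitance C_m in pF (converts an applied current in pA
        to pA/pF).
    constants, concentrations:
        Used for Nernst reversal potentials. Reversal potentials are
        recomputed from the live state when the intracellular concentration
        is a state variable, and fixed otherwise.
    state_layout:
        Ordered state-variable names; must contain ``"V"`` and every gate.
    initial_state:
        Mapping name -> initial value, complete over ``state_layout``.
    extra_currents:
        Optional hook ``f(view, V, E, params) -> {name: pA/pF}`` for currents
        outside the gated-ohmic algebra (rectifiers, pumps, exchangers).
        They are added to the membrane balance.
    non_gating_dynamics:
        Optional hook ``f(view, V, currents, E, params) -> {state: d/dt}``
        providing derivatives for every state that is neither V nor a gate.
    voltage_rhs:
        Optional override
        ``f(view, V, currents, i_app_density, params, gate_derivs) -> dV/dt``
        (used by analytic test fixtures where V is a readout, not a balance).
    """

    def __init__(
        self,
        gates: Sequence[GateSpec],
        channels: Sequence[ChannelSpec],
        capacitance: float,
        constants: PhysicalConstants,
        concentrations: IonConcentrations,
        state_layout: Sequence[str],
        initial_state: Mapping[str, float],
        extra_currents: Callable | None = None,
        non_gating_dynamics: Callable | None = None,
        voltage_rhs: Callable | None = None,
        params: Mapping[str, float] | None = None,
        name: str = "model",
    ):
        self.gates = list(gates)
        self.channels = list(channels)
        self.capacitance = float(capacitance)
        self.constants = constants
        self.concentrations = concentrations
        self.state_layout = list(state_layout)
        self.initial_state = dict(initial_state)
        self.extra_currents = extra_currents
        self.non_gating_dynamics = non_gating_dynamics
        self.voltage_rhs = voltage_rhs
        self.params = dict(params or {})
        self.name = name
        self._validate()
        self._compile()

    # -- validation ------------------------------------------------------
    def _validate(self):
        if self.capacitance <= 0:
            raise ConfigurationError("capacitance must be > 0 pF")
        if len(set(self.state_layout)) != len(self.state_layout):
            raise ConfigurationError("state_layout contains duplicate names")
        if "V" not in self.state_layout:
            raise ConfigurationError("state_layout must contain 'V'")
        names = set(self.state_layout)
        gate_names = [g.name for g in self.gates]
        if len(set(gate_names)) != len(gate_names):
            raise ConfigurationError("duplicate gate names")
        for g in self.gates:
            if g.name not in names:
                raise ConfigurationError(f"gate {g.name!r} missing from state_layout")
            if g.driver != "V" and g.driver not in names:
                raise ConfigurationError(
                    f"gate {g.name!r}: driver {g.driver!r} is not a state variable"
                )
        gset = set(gate_names)
        for ch in self.channels:
            for g, _ in ch.gate_powers:
                if g not in gset:
                    raise ConfigurationError(
                        f"channel {ch.name!r} references undefined gate {g!r}"
                    )
            if ch.ion is not None and ch.ion not in self.concentrations.external:
                raise ConfigurationError(
                    f"channel {ch.name!r}: no extracellular concentration for "
                    f"ion {ch.ion!r}"
                )
        missing = [s for s in self.state_layout if s not in self.initial_state]
        if missing:
            raise ConfigurationError(f"initial_state missing entries: {missing}")

    # -- compiled arrays for fast RHS evaluation -------------------------
    def _compile(self):
        self.index = {s: i for i, s in enumerate(self.state_layout)}
        self._iv = self.index["V"]
        ng = len(self.gates)
        self._gate_idx = np.array([self.index[g.name] for g in self.gates], dtype=int)
        self._driver_idx = np.array(
            [self.index[g.driver] for g in self.gates], dtype=int
        )
        self._a1 = np.array([g.ss_a1 for g in self.gates])
        self._a2 = np.array([g.ss_a2 for g in self.gates])
        mt = max((len(g.tau_terms) for g in self.gates), default=1)
        B = np.zeros((ng, mt))
        C = np.zeros((ng, mt))
        D = np.full((ng, mt), -EXP_CLAMP)  # exp -> ~0 for padding rows
        for i, g in enumerate(self.gates):
            for j, (b, c, d) in enumerate(g.tau_terms):
                B[i, j], C[i, j], D[i, j] = b, c, d
        self._tauB, self._tauC, self._tauD = B, C, D
        self._nongate_idx = [
            self.index[s]
            for s in self.state_layout
            if s != "V" and s not in {g.name for g in self.gates}
        ]
        self._nongate_names = [self.state_layout[i] for i in self._nongate_idx]
        # fixed reversal potentials, recomputed per step only when dynamic
        self._dyn_ions = {
            ion: self.index[st]
            for ion, st in self.concentrations.internal_states.items()
        }
        self._fixed_E = {}
        for ch in self.channels:
            if ch.ion is not None and ch.ion not in self._dyn_ions:
                self._fixed_E[ch.ion] = nernst(
                    ION_VALENCE[ch.ion],
                    self.concentrations.external[ch.ion],
                    self.concentrations.internal[ch.ion],
                    self.constants,
                )

    # -- public API ------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_layout)

    def initial_vector(self) -> np.ndarray:
        return np.array([self.initial_state[s] for s in self.state_layout])

    def reversal_potentials(self, y: np.ndarray) -> dict[str, float]:
        E = dict(self._fixed_E)
        for ion, idx in self._dyn_ions.items():
            c_in = y[idx]
            if c_in <= 0:
                raise DomainError(
                    f"intracellular [{ion}] = {c_in:g} mM is non-positive"
                )
            E[ion] = nernst(
                ION_VALENCE[ion],
                self.concentrations.external[ion],
                c_in,
                self.constants,
            )
        return E

    def currents(self, y: np.ndarray) -> dict[str, float]:
        """All membrane currents (pA/pF) at state ``y``, by name."""
        V = y[self._iv]
        E = self.reversal_potentials(y)
        view = StateView(y, self.index)
        out: dict[str, float] = {}
        for ch in self.channels:
            e = ch.e_fixed if ch.e_fixed is not None else E[ch.ion]
            open_frac = 1.0
            for g, p in ch.gate_powers:
                open_frac *= y[self.index[g]] ** p
            out[ch.name] = ch.conductance * open_frac * (V - e)
        if self.extra_currents is not None:
            out.update(self.extra_currents(view, V, E, self.params))
        return out

    def rhs(
        self,
        t: float,
        y: np.ndarray,
        i_app: float = 0.0,
        tau_scale: np.ndarray | None = None,
    ) -> np.ndarray:
        """Time derivative of the full state vector.

        ``i_app`` is the applied current in pA (divided by C_m internally);
        ``tau_scale`` multiplies each gate's time constant (the perturbation
        hook of the contribution analysis).
        """
        dydt = np.zeros_like(y)
        V = y[self._iv]
        drv = y[self._driver_idx]
        xinf = 1.0 / (1.0 + _safe_exp(self._a1 * drv + self._a2))
        inv_tau = (
            self._tauB * _safe_exp(self._tauC * drv[:, None] + self._tauD)
        ).sum(axis=1)
        if tau_scale is not None:
            inv_tau = inv_tau / tau_scale
        dydt[self._gate_idx] = (xinf - y[self._gate_idx]) * inv_tau

        currents = self.currents(y)
        total = 0.0
        for v in currents.values():
            total += v
        view = StateView(y, self.index)
        i_density = i_app / self.capacitance
        if self.voltage_rhs is not None:
            gate_derivs = {
                g.name: dydt[i] for g, i in zip(self.gates, self._gate_idx)
            }
            dydt[self._iv] = self.voltage_rhs(
                view, V, currents, i_density, self.params, gate_derivs
            )
        else:
            dydt[self._iv] = -total + i_density

        if self._nongate_idx:
            if self.non_gating_dynamics is None:
                raise ConfigurationError(
                    f"states {self._nongate_names} need non_gating_dynamics"
                )
            E = self.reversal_potentials(y)
            extra = self.non_gating_dynamics(view, V, currents, E, self.params)
            for nm, i in zip(self._nongate_names, self._nongate_idx):
                dydt[i] = extra[nm]

        if not np.all(np.isfinite(dydt)):
            bad = [
                self.state_layout[i]
                for i in np.nonzero(~np.isfinite(dydt))[0]
            ]
            raise DomainError(
                f"non-finite derivative for state(s) {bad} at t={t:g} ms"
            )
        return dydt

    def gate(self, name: str) -> GateSpec:
        for g in self.gates:
            if g.name == name:
                return g
        raise KeyError(name)

    def gate_names(self) -> list[str]:
        return [g.name for g in self.gates]

    def tau_scale_vector(self, gate: str | None = None, delta: float = 0.0) -> np.ndarray:
        """Vector multiplying each gate's tau; (1+delta) for ``gate``, 1 elsewhere."""
        v = np.ones(len(self.gates))
        if gate is not None:
            names = self.gate_names()
            if gate not in names:
                raise KeyError(f"unknown gate {gate!r}")
            v[names.index(gate)] = 1.0 + delta
        return v
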