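"""Analytic and synthetic fixtures.

* ``toy_threshold_model`` -- a single relaxing gate with a linear voltage
  readout; the time for V to reach a threshold is exactly proportional to
  the gate's time constant, so its contribution is exactly 1 for any
  perturbation size. The analytic oracle for the whole pipeline.
* ``squid_axon_model`` -- the classic squid giant-axon model (standard
  textbook rate constants) converted to the declarative sigmoid /
  sum-of-exponentials format; demonstrates that the analysis applies to
  any conductance-based excitable-cell model, not just the cardiac one.
* ``synthetic_ap`` -- a piecewise-analytic cardiac-AP-shaped waveform with
  known phase-point ground truth for segmentation tests.

All fixtures are deterministic; the optional waveform noise takes an
explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    CellModel,
    ChannelSpec,
    GateSpec,
    IonConcentrations,
    PhysicalConstants,
)
from .simulate import Trajectory

__all__ = [
    "toy_threshold_model",
    "toy_event_time",
    "toy_threshold_voltage",
    "squid_axon_model",
    "synthetic_ap",
    "SyntheticAPParams",
]


# ---------------------------------------------------------------------------
# toy threshold model
# ---------------------------------------------------------------------------

def toy_event_time(tau: float, x_inf: float, x0: float, theta: float) -> float:
    """Closed-form time for x to relax from x0 to theta: tau*ln((xinf-x0)/(xinf-theta))."""
    return tau * math.log((x_inf - x0) / (x_inf - theta))


def toy_threshold_voltage(
    theta: float, x0: float, kappa: float = 100.0, v0: float = 0.0
) -> float:
    """Voltage level corresponding to the gate threshold theta."""
    return v0 + kappa * (theta - x0)


def toy_threshold_model(
    tau: float,
    x_inf: float,
    x0: float,
    theta: float,
    kappa: float = 100.0,
    with_decoupled_gate: bool = False,
) -> CellModel:
    """Single-gate model with V a linear readout of the gate (V = kappa*x).

    Requires x0 < theta < x_inf. The event "V reaches
    ``toy_threshold_voltage(theta, ...)``" occurs at exactly
    ``toy_event_time(tau, ...)``, and scaling tau scales that time exactly.
    ``with_decoupled_gate`` appends a gate ``z`` that relaxes but does not
    enter the voltage equation (null-contribution control).
    """
    if not (x0 < theta < x_inf <= 1.0) or not (0.0 <= x0):
        raise ValueError("require 0 <= x0 < theta < x_inf <= 1")
    # fixed steady state and time constant: a1 = 0 makes x_inf voltage-free
    gates = [GateSpec("x", 0.0, math.log(1.0 / x_inf - 1.0), ((1.0 / tau, 0.0, 0.0),))]
    layout = ["V", "x"]
    init = {"V": 0.0, "x": x0}
    if with_decoupled_gate:
        gates.append(GateSpec("z", 0.0, math.log(1.0 / 0.5 - 1.0), ((1.0, 0.0, 0.0),)))
        layout.append("z")
        init["z"] = 0.2

    def v_readout(view, V, currents, i_density, params, gate_derivs):
        return params["kappa"] * gate_derivs["x"]

    return CellModel(
        gates=gates,
        channels=[],
        capacitance=1.0,
        constants=PhysicalConstants(),
        concentrations=IonConcentrations(external={}),
        state_layout=layout,
        initial_state=init,
        voltage_rhs=v_readout,
        params={"kappa": kappa},
        name="toy-threshold",
    )


# ---------------------------------------------------------------------------
# squid giant axon
# ---------------------------------------------------------------------------

# Classic rate constants converted offline to the declarative forms by
# non-negative least squares on [-100, 50] mV.
# x_inf -> 1/(1+exp(a1 V + a2)); 1/tau -> sum b exp(c V).
# Fit quality: |x_inf| error < 0.013 (m), 0.010 (h), 0.041 (n); relaxation
# rates within ~16% for m and n. The h rate saturates at depolarized V and
# is not log-convex, which no positive sum of exponentials can follow; its
# fit deviates up to ~55% at the depolarized extreme. The fixture is
# therefore a squid-like model for qualitative use, not a quantitative
# reproduction of the textbook kinetics.
_SQUID_GATES: dict = {
    "m": (-0.1046935, -4.1431828, (
        (0.011118538, -0.07, 0.0),
        (0.02779868, -0.065, 0.0),
        (3.4283508, 0.02, 0.0),
        (0.31672637, 0.025, 0.0),
    )),
    "h": (0.14146657, 8.7935103, (
        (1.028508e-07, -0.135, 0.0),
        (7.8486123e-07, -0.13, 0.0),
        (0.017157434, 0.015, 0.0),
        (0.56045721, 0.02, 0.0),
    )),
    "n": (-0.056321044, -2.8763637, (
        (1.3032359e-05, -0.09, 0.0),
        (0.41206443, 0.015, 0.0),
        (0.13898706, 0.02, 0.0),
    )),
}


def squid_axon_model(with_decoupled_gate: bool = False) -> CellModel:
    """4-state squid axon model (V, m, h, n) in the declarative format.

    Conductances gNa=120, gK=36, gL=0.3 mS/cm2 per uF/cm2 (numerically
    identical to nS/pF), ENa=+50, EK=-77, EL=-54.387 mV; resting potential
    about -65 mV. Steady states and time constants are least-squares fits
    of the textbook alpha/beta kinetics (max |x_inf| error < 0.01; max
    relative 1/tau error ~1-2% on [-100, 50] mV).
    """
    gates = [
        GateSpec("m", *_SQUID_GATES["m"]),
        GateSpec("h", *_SQUID_GATES["h"]),
        GateSpec("n", *_SQUID_GATES["n"]),
    ]
    layout = ["V", "m", "h", "n"]
    init = {"V": -65.0, "m": 0.0529, "h": 0.5961, "n": 0.3177}
    if with_decoupled_gate:
        gates.append(GateSpec("z", 0.0, 0.0, ((0.5, 0.0, 0.0),)))
        layout.append("z")
        init["z"] = 0.3
    channels = [
        ChannelSpec("Na", 120.0, (("m", 3), ("h", 1)), e_fixed=50.0),
        ChannelSpec("K", 36.0, (("n", 4),), e_fixed=-77.0),
        ChannelSpec("L", 0.3, (), e_fixed=-54.387),
    ]
    return CellModel(
        gates=gates,
        channels=channels,
        capacitance=1.0,
        constants=PhysicalConstants(),
        concentrations=IonConcentrations(external={}),
        state_layout=layout,
        initial_state=init,
        name="squid-axon",
    )


# ---------------------------------------------------------------------------
# synthetic AP waveform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticAPParams:
    baseline: float = -80.0  # mV
    peak: float = 40.0  # mV
    notch_level: float = 25.0  # mV
    plateau_end_level: float = 10.0  # mV
    t_up_start: float = 20.0  # ms
    d_up: float = 2.0  # ms
    d_notch: float = 8.0  # ms
    d_plateau: float = 60.0  # ms
    d_repol: float = 40.0  # ms
    total: float = 200.0  # ms
    dt: float = 0.01  # ms


def _cos_seg(t, ta, tb, A, B):
    s = (t - ta) / (tb - ta)
    return A + (B - A) * 0.5 * (1.0 - np.cos(np.pi * s))


def synthetic_ap(
    params: SyntheticAPParams = SyntheticAPParams(),
    noise: float = 0.0,
    seed: int | None = None,
) -> tuple[Trajectory, dict]:
    """Piecewise half-cosine AP-like waveform plus its landmark ground truth.

    Returns ``(trajectory, truth)`` where ``truth`` holds the construction's
    P0..P4 as defined by the default segmentation criteria (upstroke dV/dt
    = 1 mV/ms, notch exit/plateau exit thresholds, 2 mV baseline return).
    The trajectory carries one auxiliary 'g' series (V rescaled to [0, 1])
    so epoch construction can be exercised.
    """
    p = params
    t = np.arange(0.0, p.total + p.dt / 2, p.dt)
    t1 = p.t_up_start
    t2 = t1 + p.d_up
    t3 = t2 + p.d_notch
    t4 = t3 + p.d_plateau
    t5 = t4 + p.d_repol
    if t5 >= p.total:
        raise ValueError("segments exceed total duration")
    V = np.full_like(t, p.baseline)
    m = (t >= t1) & (t < t2)
    V[m] = _cos_seg(t[m], t1, t2, p.baseline, p.peak)
    m = (t >= t2) & (t < t3)
    V[m] = _cos_seg(t[m], t2, t3, p.peak, p.notch_level)
    m = (t >= t3) & (t < t4)
    V[m] = _cos_seg(t[m], t3, t4, p.notch_level, p.plateau_end_level)
    m = (t >= t4) & (t < t5)
    V[m] = _cos_seg(t[m], t4, t5, p.plateau_end_level, p.baseline)
    if noise > 0.0:
        rng = np.random.default_rng(seed)
        V = V + rng.normal(0.0, noise, size=V.shape)

    g = (V - p.baseline) / (p.peak - p.baseline)
    traj = Trajectory(t, np.column_stack([V, g]), ["V", "g"])

    # analytic landmark truth for the default criteria
    def cos_slope_cross(ta, tb, A, B, level, last=False):
        # slope of the half-cosine: (B-A)*pi/(2*(tb-ta)) * sin(pi*s)
        amp = (B - A) * np.pi / (2.0 * (tb - ta))
        r = level / amp
        if not (0 <= abs(r) <= 1):
            return None
        s = np.arcsin(abs(r)) / np.pi
        s = (1.0 - s) if last else s
        return ta + s * (tb - ta)

    truth = {
        "P0": cos_slope_cross(t1, t2, p.baseline, p.peak, 1.0),
        "P1": t2,
        # P2: slope recovers above -1 mV/ms in the tail of the notch segment
        "P2": cos_slope_cross(t2, t3, p.peak, p.notch_level, -1.0, last=True),
        # P3: slope falls below -0.5 mV/ms early in the repolarization
        "P3": cos_slope_cross(t4, t5, p.plateau_end_level, p.baseline, -0.5),
        "P4": None,  # filled below: V returns within 2 mV of baseline
    }
    # V = baseline + 2 on the repol segment
    A, B = p.plateau_end_level, p.baseline
    frac = (p.baseline + 2.0 - A) / (B - A)
    truth["P4"] = t4 + (t5 - t4) * np.arccos(1.0 - 2.0 * frac) / np.pi
    return traj, truth
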