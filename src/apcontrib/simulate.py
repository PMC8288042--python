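"""Stiff integration of cell models under stimulus protocols.

The solver is SciPy's variable-order BDF (Gear-type) implicit multistep
method; output is resampled from the solver's dense interpolant onto a
uniform grid so that derivative-based segmentation sees an evenly sampled
signal. Default tolerances are tight (rtol 1e-8, atol 1e-10) because the
contribution analysis measures small fractional changes in durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .core import CellModel

__all__ = [
    "StimulusProtocol",
    "SolverOptions",
    "Trajectory",
    "SimulationError",
    "simulate",
    "resample",
    "membrane_rhs",
]


class SimulationError(RuntimeError):
    """Integration failed; carries the last valid time and state."""

    def __init__(self, message, t_last=None, y_last=None):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last


@dataclass(frozen=True)
class StimulusProtocol:
    """Applied-current protocol.

    ``constant`` mode injects ``amplitude`` pA from ``onset`` to the end of
    the run (a sustained current-clamp step); ``pulse`` mode injects it only
    for ``duration`` ms after onset.
    """

    amplitude: float = 528.0  # pA
    onset: float = 0.0  # ms
    duration: float | None = None  # ms, pulse mode only
    total_time: float = 5000.0  # ms
    mode: str = "constant"

    def __post_init__(self):
        if self.mode not in ("constant", "pulse"):
            raise ValueError(f"unknown stimulus mode {self.mode!r}")
        if self.mode == "pulse" and self.duration is None:
            raise ValueError("pulse mode requires a duration")
        if not (self.total_time > self.onset >= 0):
            raise ValueError("require total_time > onset >= 0")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")

    def current(self, t: float) -> float:
        """Applied current (pA) at time t."""
        if t < self.onset:
            return 0.0
        if self.mode == "pulse" and t >= self.onset + self.duration:
            return 0.0
        return self.amplitude

    def breakpoints(self) -> list[float]:
        """Times at which the applied current is discontinuous."""
        pts = [self.onset] if self.onset > 0 else []
        if self.mode == "pulse":
            pts.append(self.onset + self.duration)
        return [p for p in pts if 0.0 < p < self.total_time]


@dataclass(frozen=True)
class SolverOptions:
    method: str = "BDF"
    rtol: float = 1e-8
    atol: float = 1e-10
    output_dt: float = 0.001  # ms
    max_step: float = np.inf

    def __post_init__(self):
        if self.output_dt <= 0 or self.rtol <= 0 or self.atol <= 0:
            raise ValueError("output_dt, rtol and atol must be > 0")

    def with_dt(self, dt: float) -> "SolverOptions":
        return replace(self, output_dt=dt)


def membrane_rhs(state, t, model: CellModel, protocol: StimulusProtocol):
    """Full state derivative at (state, t) under the protocol's current."""
    return model.rhs(t, np.asarray(state, dtype=float), i_app=protocol.current(t))


@dataclass
class Trajectory:
    """Uniformly sampled solution of a cell model.

    ``data`` is (n_times, n_states); columns follow ``names``. ``dense``
    optionally keeps the solver's piecewise interpolant for high-accuracy
    state look-ups between grid points.
    """

    t: np.ndarray
    data: np.ndarray
    names: list[str]
    protocol: StimulusProtocol | None = None
    options: SolverOptions | None = None
    dense: object = None
    index: dict = field(init=False)

    def __post_init__(self):
        self.index = {n: i for i, n in enumerate(self.names)}
        if self.data.shape != (len(self.t), len(self.names)):
            raise ValueError("data shape does not match t/names")
        dt = np.diff(self.t)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-9 * dt[0] + 1e-12):
            raise ValueError("time grid must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trajectory contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def V(self) -> np.ndarray:
        return self.state("V")

    def state(self, name: str) -> np.ndarray:
        return self.data[:, self.index[name]]

    def state_at(self, t: float) -> np.ndarray:
        """Full state vector at an arbitrary time within the span."""
        if not (self.t[0] - 1e-9 <= t <= self.t[-1] + 1e-9):
            raise ValueError(f"t={t} outside trajectory span")
        if self.dense is not None:
            return np.asarray(self.dense(t), dtype=float)
        i = min(int(np.searchsorted(self.t, t)), len(self.t) - 1)
        lo, hi = max(i - 2, 0), min(i + 2, len(self.t))
        cs = CubicSpline(self.t[lo:hi], self.data[lo:hi], axis=0)
        return cs(t)

    def value_at(self, name: str, t: float) -> float:
        return float(self.state_at(t)[self.index[name]])

    def window(self, t0: float, t1: float) -> "Trajectory":
        """Sub-trajectory on [t0, t1] (grid-aligned)."""
        m = (self.t >= t0 - 1e-12) & (self.t <= t1 + 1e-12)
        return Trajectory(
            self.t[m], self.data[m], list(self.names), self.protocol, self.options,
            dense=self.dense,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=self.names)
        df.insert(0, "t", self.t)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        t = df.pop("t").to_numpy()
        return cls(t, df.to_numpy(), list(df.columns))


class _Chain:
    """Piecewise dense output over chained integration segments."""

    def __init__(self, sols):
        self.sols = sols
        self.edges = np.array([s.t[-1] for s in sols])

    def __call__(self, t):
        i = int(np.searchsorted(self.edges[:-1], t))
        return self.sols[i].sol(t)


def simulate(
    model: CellModel,
    protocol: StimulusProtocol,
    options: SolverOptions = SolverOptions(),
    t_end: float | None = None,
    tau_scale: np.ndarray | None = None,
    y0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate ``model`` under ``protocol`` and resample to a uniform grid.

    ``t_end`` truncates the run (defaults to ``protocol.total_time``);
    ``tau_scale`` is forwarded to the RHS (time-constant perturbations);
    ``y0`` overrides the model's initial state.
    """
    t_final = protocol.total_time if t_end is None else float(t_end)
    y = model.initial_vector() if y0 is None else np.asarray(y0, dtype=float)
    edges = [0.0] + [b for b in protocol.breakpoints() if b < t_final] + [t_final]

    sols = []
    for a, b in zip(edges[:-1], edges[1:]):
        i_app = protocol.current(0.5 * (a + b))

        def f(t, yy):
            return model.rhs(t, yy, i_app=i_app, tau_scale=tau_scale)

        sol = solve_ivp(
            f, (a, b), y, method=options.method, rtol=options.rtol,
            atol=options.atol, max_step=options.max_step, dense_output=True,
        )
        if not sol.success:
            raise SimulationError(
                f"solver failed at t={sol.t[-1]:.6g} ms: {sol.message}",
                t_last=sol.t[-1], y_last=sol.y[:, -1],
            )
        sols.append(sol)
        y = sol.y[:, -1]

    chain = _Chain(sols)
    n = int(round(t_final / options.output_dt))
    t_grid = np.arange(n + 1) * options.output_dt
    t_grid = t_grid[t_grid <= t_final + 1e-12]
    data = np.empty((len(t_grid), model.n_states))
    # evaluate segment-wise to keep the interpolant lookups cheap
    for i, s in enumerate(sols):
        lo = 0.0 if i == 0 else s.t[0]
        m = (t_grid >= lo - 1e-12) & (t_grid <= s.t[-1] + 1e-12)
        if m.any():
            data[m] = s.sol(t_grid[m]).T
    # physicality guard: open probabilities must stay in [0, 1]
    for g in model.gates:
        col = data[:, model.index[g.name]]
        if col.min() < -1e-6 or col.max() > 1.0 + 1e-6:
            raise SimulationError(
                f"gate {g.name!r} left [0, 1] (range {col.min():.3g}.."
                f"{col.max():.3g})"
            )
    return Trajectory(
        t_grid, data, list(model.state_layout), protocol, options, dense=chain
    )


def resample(traj: Trajectory, dt: float) -> Trajectory:
    """Cubic re-interpolation onto a new uniform grid with the same origin."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    span = traj.t[-1] - traj.t[0]
    if dt > span:
        raise ValueError(f"dt={dt} exceeds trajectory span {span}")
    if abs(dt - traj.dt) < 1e-15:
        return traj
    n = int(np.floor(span / dt + 1e-9))
    t_new = traj.t[0] + np.arange(n + 1) * dt
    cs = CubicSpline(traj.t, traj.data, axis=0)
    return Trajectory(
        t_new, cs(t_new), list(traj.names), traj.protocol, traj.options,
        dense=traj.dense,
    )
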