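"""The tau-perturbation contribution measure.

For a gating variable ``x`` and a region of the AP with reference duration
``D``, the gate's time constant is scaled by ``(1 + delta)`` for a fresh
integration started from the reference state at the region's start; the run
stops when V crosses the reference end-voltage in the reference direction,
giving the perturbed duration ``D'``. The contribution is the elasticity

    C = ((D' - D) / D) / delta

so ``C > 0`` means slowing the gate lengthens the region. Regions are the
epochs of the segmentation; phase totals sum per-epoch elasticities, while
IoIs and APD regions pool durations:

    C_summed = sum_k C_k
    C_pooled = (sum_k (D'_k - D_k) / sum_k D_k) / delta

Signs follow the feedback convention: a gate moving in the same direction
as V through a channel with positive reversal potential contributes
positively; the sign flips for opposite motion and for negative-reversal
(K+) channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import CellModel, ION_VALENCE, nernst
from .segment import (
    Epoch,
    EpochSet,
    PhasePoints,
    RegionSet,
    SegmentationCriteria,
    apd,
    build_epochs,
    make_iois,
    segment_phases,
)
from .simulate import SolverOptions, StimulusProtocol, Trajectory, simulate

__all__ = [
    "Perturbation",
    "PerturbationError",
    "ContributionResult",
    "ContributionTable",
    "AnalysisSettings",
    "perturbed_duration",
    "contribution_interval",
    "aggregate_summed",
    "aggregate_pooled",
    "expected_sign",
    "run_full_analysis",
]


class PerturbationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Perturbation:
    """A fractional slowing (delta > 0) or speeding of one gate's tau."""

    gate: str
    delta: float = 0.10
    start_time: float = 0.0

    def __post_init__(self):
        if self.delta == 0 or 1.0 + self.delta <= 0:
            raise ValueError("require delta != 0 and 1 + delta > 0")


@dataclass(frozen=True)
class ContributionResult:
    gate: str
    label: str
    t_start: float
    t_end: float
    duration: float  # reference D (ms)
    perturbed: float  # D' (ms)
    delta: float
    mode: str = "interval"  # interval | summed | pooled
    clipped: bool = False  # end level was never reached; extremum time used
    degenerate: bool = False  # V flat across the interval; C forced to 0

    @property
    def C(self) -> float:
        if self.degenerate or self.duration == 0:
            return 0.0
        return (self.perturbed - self.duration) / self.duration / self.delta


def _perturbed_run(
    model: CellModel,
    ref: Trajectory,
    gate: str,
    interval: tuple[float, float],
    delta: float,
    options: SolverOptions,
    horizon_factor: float = 50.0,
) -> tuple[float, bool, bool]:
    """Return (perturbed duration, clipped, degenerate) for one interval."""
    t_start, t_end = interval
    D = t_end - t_start
    if D <= 0:
        raise ValueError("interval must have positive duration")
    if delta == 0.0:
        return D, False, False

    y0 = ref.state_at(t_start)
    iv = ref.index["V"]
    v_start = y0[iv]
    v_end = ref.value_at("V", t_end)
    dv = v_end - v_start
    # flat interval: no measurable end level; report the reference duration
    if abs(dv) < 1e-9:
        return D, False, True
    direction = 1.0 if dv > 0 else -1.0

    tau_scale = model.tau_scale_vector(gate, delta)
    protocol = ref.protocol or StimulusProtocol(amplitude=0.0, total_time=np.inf)

    def f(t, y):
        return model.rhs(t, y, i_app=protocol.current(t), tau_scale=tau_scale)

    def hit_level(t, y):
        return y[iv] - v_end

    hit_level.terminal = True
    hit_level.direction = direction

    # reversal guard: V turns around (beyond numerical wiggle) before the
    # level is reached -- take the extremum as the closest approach
    rate_guard = 0.02 * abs(dv) / D

    def reversed_(t, y):
        return direction * f(t, y)[iv] + rate_guard

    reversed_.terminal = True
    reversed_.direction = -1.0

    sol = solve_ivp(
        f,
        (t_start, t_start + horizon_factor * D),
        y0,
        method=options.method,
        rtol=options.rtol,
        atol=options.atol,
        events=(hit_level, reversed_),
        dense_output=False,
    )
    if not sol.success:
        raise PerturbationError(
            f"integration failed while perturbing gate {gate!r} on "
            f"[{t_start:g}, {t_end:g}] ms: {sol.message}"
        )
    if len(sol.t_events[0]):
        return float(sol.t_events[0][0]) - t_start, False, False
    if len(sol.t_events[1]):
        return float(sol.t_events[1][0]) - t_start, True, False
    raise PerturbationError(
        f"unbounded perturbation effect: gate {gate!r} slowed by "
        f"{delta:+.3g} never reaches the end level {v_end:.3f} mV of "
        f"[{t_start:g}, {t_end:g}] ms within {horizon_factor:g}x the "
        f"reference duration"
    )


def perturbed_duration(
    model: CellModel,
    ref: Trajectory,
    gate: str,
    interval: tuple[float, float],
    delta: float,
    options: SolverOptions = SolverOptions(),
) -> float:
    """Perturbed duration D' (ms) of ``interval`` with gate tau scaled by 1+delta."""
    dur, _, _ = _perturbed_run(model, ref, gate, interval, delta, options)
    return dur


def contribution_interval(
    model: CellModel,
    ref: Trajectory,
    gate: str,
    interval: tuple[float, float],
    delta: float = 0.10,
    options: SolverOptions = SolverOptions(),
    label: str = "",
) -> ContributionResult:
    """Epoch/interval-level contribution C = ((D'-D)/D)/delta."""
    t_start, t_end = interval
    dur, clipped, degenerate = _perturbed_run(
        model, ref, gate, interval, delta, options
    )
    return ContributionResult(
        gate=gate,
        label=label or f"[{t_start:g},{t_end:g}]",
        t_start=t_start,
        t_end=t_end,
        duration=t_end - t_start,
        perturbed=dur,
        delta=delta,
        clipped=clipped,
        degenerate=degenerate,
    )


def _check_shared(results: Sequence[ContributionResult]):
    if not results:
        raise ValueError("no epoch-level results to aggregate")
    gates = {r.gate for r in results}
    deltas = {r.delta for r in results}
    if len(gates) > 1 or len(deltas) > 1:
        raise ValueError("aggregation requires a single gate and delta")


def aggregate_summed(results: Sequence[ContributionResult]) -> float:
    """Phase-style total: the sum of per-epoch elasticities."""
    _check_shared(results)
    return float(sum(r.C for r in results))


def aggregate_pooled(results: Sequence[ContributionResult]) -> float:
    """Duration-weighted total: fractional change of the pooled duration."""
    _check_shared(results)
    D = sum(r.duration for r in results)
    dD = sum(r.perturbed - r.duration for r in results if not r.degenerate)
    return float(dD / D / results[0].delta)


def expected_sign(
    ion: str | None,
    gate_direction: str,
    V_direction: str,
    E_sign: str,
) -> str:
    """Expected sign of C from the feedback rule.

    Same direction of gate and voltage with a positive reversal potential
    gives '+'; opposite direction gives '-'; both flip when the reversal
    potential is negative.
    """
    if gate_direction not in ("rising", "falling"):
        raise ValueError(f"bad gate_direction {gate_direction!r}")
    if V_direction not in ("depolarizing", "repolarizing"):
        raise ValueError(f"bad V_direction {V_direction!r}")
    if E_sign not in ("positive", "negative"):
        raise ValueError(f"bad E_sign {E_sign!r}")
    same = (gate_direction == "rising") == (V_direction == "depolarizing")
    positive = same == (E_sign == "positive")
    return "+" if positive else "-"


@dataclass(frozen=True)
class AnalysisSettings:
    """Everything run_full_analysis needs beyond model and protocol."""

    delta: float = 0.10
    t_end: float | None = 250.0  # analysis window (ms); None = protocol total
    n_ioi: int = 4
    apd_fractions: tuple[int, ...] = (20, 50, 90)
    min_epoch_ms: float = 0.05
    gates: tuple[str, ...] | None = None  # None = every gate in the model
    solver: SolverOptions = field(default_factory=SolverOptions)
    criteria: SegmentationCriteria = field(default_factory=SegmentationCriteria)
    regions: tuple[str, ...] = ("phases", "iois", "apd")


@dataclass
class ContributionTable:
    """Per-gate x per-region contribution values with full provenance."""

    table: pd.DataFrame  # rows = gates, columns = region labels
    modes: dict[str, str]  # region label -> aggregation mode
    epoch_results: dict[str, list[ContributionResult]]
    regions: RegionSet
    errors: dict[tuple[str, str], str]
    sign_diagnostics: pd.DataFrame | None = None
    delta: float = 0.10

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="gate")

    def clipped_matrix(self, lo: float = -0.01, hi: float = 0.01) -> pd.DataFrame:
        """Heatmap export: values clipped to the display range [lo, hi]."""
        return self.table.clip(lower=lo, upper=hi)

    def to_json(self) -> dict:
        return {
            "delta": self.delta,
            "values": {
                g: {c: _none_if_nan(self.table.loc[g, c]) for c in self.table.columns}
                for g in self.table.index
            },
            "modes": self.modes,
            "epochs": {
                g: [
                    {
                        "label": r.label, "t_start": r.t_start, "t_end": r.t_end,
                        "D": r.duration, "D_perturbed": r.perturbed, "C": r.C,
                        "clipped": r.clipped, "degenerate": r.degenerate,
                    }
                    for r in rs
                ]
                for g, rs in self.epoch_results.items()
            },
            "errors": {f"{g}/{reg}": msg for (g, reg), msg in self.errors.items()},
        }


def _none_if_nan(v):
    return None if pd.isna(v) else float(v)


def _gate_ion(model: CellModel, gate: str):
    """(ion, E sign) of the first channel using the gate, or (None, None)."""
    for ch in model.channels:
        if any(g == gate for g, _ in ch.gate_powers):
            if ch.e_fixed is not None:
                return None, ("positive" if ch.e_fixed > 0 else "negative")
            c_in = model.concentrations.internal.get(ch.ion)
            if ch.ion in model.concentrations.internal_states:
                st = model.concentrations.internal_states[ch.ion]
                c_in = model.initial_state[st]
            e = nernst(
                ION_VALENCE[ch.ion], model.concentrations.external[ch.ion],
                c_in, model.constants,
            )
            return ch.ion, ("positive" if e > 0 else "negative")
    return None, None


def run_full_analysis(
    model: CellModel,
    protocol: StimulusProtocol,
    settings: AnalysisSettings = AnalysisSettings(),
    ref: Trajectory | None = None,
) -> ContributionTable:
    """Simulate, segment, and compute the full contribution table.

    Phase totals use the summed aggregation; IoIs and APD regions use the
    pooled aggregation. A failing (gate, region) cell is recorded in
    ``errors`` and left NaN; the analysis continues.
    """
    if ref is None:
        ref = simulate(model, protocol, settings.solver, t_end=settings.t_end)
    phases = segment_phases(ref, settings.criteria)
    iois = make_iois(phases, settings.n_ioi)
    apd_marks = {
        f: apd(ref, f, phases=phases) for f in settings.apd_fractions
    }

    gates = list(settings.gates) if settings.gates else model.gate_names()
    columns = (
        [f"P{i}" for i in range(4)]
        + list(iois.keys())
        + [f"AP{f}" for f in settings.apd_fractions]
    )
    modes = {c: ("summed" if c in ("P0", "P1", "P2", "P3") else "pooled")
             for c in columns}
    tab = pd.DataFrame(np.nan, index=gates, columns=columns)
    errors: dict[tuple[str, str], str] = {}
    epoch_results: dict[str, list[ContributionResult]] = {}
    epoch_sets: dict[str, EpochSet] = {}
    diag_rows = []

    # IoI and APD aggregation pools the epochs lying under each region;
    # epochs straddling a region boundary are cut there (V stays monotone
    # on any sub-interval of an epoch, so the pieces remain well-posed)
    region_cuts = sorted(
        {a for a, _ in iois.values()}
        | {b for _, b in iois.values()}
        | {phases.p0 + apd_marks[f] for f in settings.apd_fractions}
    )

    def _atoms(es: EpochSet) -> list[tuple[float, float]]:
        out = []
        for ep in es.epochs:
            pts = [ep.t_start] + [
                c for c in region_cuts if ep.t_start + 1e-6 < c < ep.t_end - 1e-6
            ] + [ep.t_end]
            out.extend(zip(pts[:-1], pts[1:]))
        return out

    for gate in gates:
        es = build_epochs(ref, gate, phases, settings.min_epoch_ms)
        epoch_sets[gate] = es
        results: list[ContributionResult] = []
        for k, ep in enumerate(es.epochs, start=1):
            try:
                r = contribution_interval(
                    model, ref, gate, (ep.t_start, ep.t_end), settings.delta,
                    settings.solver, label=f"E{k}",
                )
            except PerturbationError as exc:
                errors[(gate, f"E{k}")] = str(exc)
                r = None
            if r is not None:
                results.append(r)
        epoch_results[gate] = results

        atom_results: list[ContributionResult] = []
        if set(settings.regions) & {"iois", "apd"}:
            for k, (a, b) in enumerate(_atoms(es), start=1):
                # reuse the epoch-level run when the atom is a whole epoch
                hit = next(
                    (r for r in results
                     if abs(r.t_start - a) < 1e-9 and abs(r.t_end - b) < 1e-9),
                    None,
                )
                if hit is not None:
                    atom_results.append(hit)
                    continue
                try:
                    atom_results.append(
                        contribution_interval(
                            model, ref, gate, (a, b), settings.delta,
                            settings.solver, label=f"A{k}",
                        )
                    )
                except PerturbationError as exc:
                    errors[(gate, f"A{k}")] = str(exc)

        if "phases" in settings.regions:
            for i in range(4):
                a, b = phases.phase_bounds(i)
                rs = [r for r in results if a - 1e-9 <= r.t_start < b - 1e-9]
                if rs:
                    tab.loc[gate, f"P{i}"] = aggregate_summed(rs)
        if "iois" in settings.regions:
            for lab, (a, b) in iois.items():
                rs = [
                    r for r in atom_results
                    if r.t_start >= a - 1e-9 and r.t_end <= b + 1e-9
                ]
                if rs:
                    tab.loc[gate, lab] = aggregate_pooled(rs)
        if "apd" in settings.regions:
            for f in settings.apd_fractions:
                mark = phases.p0 + apd_marks[f]
                rs = [r for r in atom_results if r.t_end <= mark + 1e-9]
                if rs:
                    tab.loc[gate, f"AP{f}"] = aggregate_pooled(rs)

        # sign-convention diagnostics per phase
        ion, e_sign = _gate_ion(model, gate)
        if e_sign is not None:
            x = ref.state(gate)
            for i in range(4):
                a, b = phases.phase_bounds(i)
                xa = float(np.interp(a, ref.t, x))
                xb = float(np.interp(b, ref.t, x))
                gdir = "rising" if xb > xa else "falling"
                vdir = "depolarizing" if i == 0 else "repolarizing"
                exp = expected_sign(ion, gdir, vdir, e_sign)
                got = tab.loc[gate, f"P{i}"]
                diag_rows.append(
                    {
                        "gate": gate, "phase": f"P{i}", "ion": ion,
                        "gate_direction": gdir, "V_direction": vdir,
                        "E_sign": e_sign, "expected": exp,
                        "C": got,
                        "consistent": (
                            None if pd.isna(got) or abs(got) < 1e-3
                            else (got > 0) == (exp == "+")
                        ),
                    }
                )

    regions = RegionSet(phases, epoch_sets, iois, apd_marks)
    return ContributionTable(
        table=tab,
        modes=modes,
        epoch_results=epoch_results,
        regions=regions,
        errors=errors,
        sign_diagnostics=pd.DataFrame(diag_rows),
        delta=settings.delta,
    )
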