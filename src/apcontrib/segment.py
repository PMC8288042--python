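"""Action-potential segmentation: phases, epochs, intervals of interest, APD.

A single AP is decomposed into

* **phases** P0..P4: depolarization (P0-P1), early repolarization (P1-P2),
  plateau (P2-P3), late repolarization and return to baseline (P3-P4);
* **epochs**: the atomic intervals between consecutive inflection points of
  the voltage trace or of one gating trajectory (plus phase boundaries and
  voltage extrema), within which V is monotone;
* **intervals of interest (IoIs)**: equal quarters of each phase;
* APD20/50/90 repolarization marks.

Phase-point criteria operate on dV/dt and are fully overridable; the
defaults were tuned on the bundled rat ventricular AP and on synthetic
waveforms (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .simulate import Trajectory

__all__ = [
    "SegmentationError",
    "SegmentationCriteria",
    "PhasePoints",
    "Epoch",
    "EpochSet",
    "RegionSet",
    "second_derivative_sign_changes",
    "segment_phases",
    "build_epochs",
    "apd",
    "make_iois",
]

PHASE_LABELS = ["P0", "P1", "P2", "P3"]


class SegmentationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SegmentationCriteria:
    """Thresholds of the automatic phase-point detection (all overridable).

    upstroke_dvdt:
        P0 = last time before the peak where dV/dt rises through this value
        (mV/ms) above the pre-upstroke baseline drift.
    notch_exit_dvdt:
        P2 = first time after the rapid early-repolarization dip where dV/dt
        recovers above this value (mV/ms).
    plateau_exit_dvdt:
        P3 = first time after P2 where dV/dt falls below this value and
        stays below it for ``sustain_ms``.
    baseline_return_mv:
        P4 = time V re-enters this band (mV) around the pre-upstroke
        baseline, capped at the 99%-repolarization time.
    explicit:
        Mapping like ``{"P2": 76.0}``; explicit user times win over the
        automatic criteria.
    """

    upstroke_dvdt: float = 1.0
    notch_exit_dvdt: float = -1.0
    plateau_exit_dvdt: float = -0.5
    sustain_ms: float = 0.5
    baseline_return_mv: float = 2.0
    explicit: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class PhasePoints:
    """The five phase-delimiting times (ms) plus waveform anchors."""

    p0: float
    p1: float
    p2: float
    p3: float
    p4: float
    baseline: float = np.nan  # V just before the upstroke (mV)
    peak: float = np.nan  # V at P1 (mV)

    def __post_init__(self):
        ts = self.times()
        if not np.all(np.diff(ts) > 0):
            raise SegmentationError(f"phase points must be increasing, got {ts}")

    def times(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2, self.p3, self.p4])

    def phase_bounds(self, i: int) -> tuple[float, float]:
        ts = self.times()
        return float(ts[i]), float(ts[i + 1])

    def as_dict(self) -> dict:
        return {
            "P0": self.p0, "P1": self.p1, "P2": self.p2, "P3": self.p3,
            "P4": self.p4, "baseline_mV": self.baseline, "peak_mV": self.peak,
        }


@dataclass(frozen=True)
class Epoch:
    t_start: float
    t_end: float
    V_start: float
    V_end: float
    monotone: bool  # True when V is monotone within the epoch
    phase: int  # 0..3

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class EpochSet:
    gate: str
    epochs: tuple[Epoch, ...]

    def in_phase(self, i: int) -> list[Epoch]:
        return [e for e in self.epochs if e.phase == i]

    def starting_in(self, t0: float, t1: float) -> list[Epoch]:
        """Epochs assigned to [t0, t1): an epoch belongs to the interval
        containing its start time."""
        return [e for e in self.epochs if t0 - 1e-9 <= e.t_start < t1 - 1e-9]


def second_derivative_sign_changes(
    series: np.ndarray,
    dt: float,
    tol: float,
    t0: float = 0.0,
    smooth: int = 1,
) -> np.ndarray:
    """Times where the second derivative crosses zero with real excursions.

    The second derivative is the central difference; a crossing is reported
    only between excursions beyond ``+tol`` and ``-tol`` (hysteresis), which
    suppresses numerical chatter on flat stretches. Crossing times are
    linearly interpolated. ``smooth`` > 1 applies a moving average of that
    many samples to the second derivative first.
    """
    f = np.asarray(series, dtype=float)
    if len(f) < 5:
        raise ValueError("series must have at least 5 samples")
    d2 = np.empty_like(f)
    d2[1:-1] = (f[2:] - 2.0 * f[1:-1] + f[:-2]) / dt**2
    d2[0], d2[-1] = d2[1], d2[-2]
    if smooth > 1:
        k = np.ones(smooth) / smooth
        d2 = np.convolve(d2, k, mode="same")

    state = np.where(d2 > tol, 1, np.where(d2 < -tol, -1, 0))
    crossings = []
    last_sign = 0
    last_idx = 0
    for i in np.nonzero(state)[0]:
        s = state[i]
        if last_sign != 0 and s != last_sign:
            # locate the last raw zero crossing of d2 in (last_idx, i]
            seg = d2[last_idx : i + 1]
            flips = np.nonzero(np.sign(seg[:-1]) * np.sign(seg[1:]) < 0)[0]
            if len(flips):
                j = last_idx + flips[-1]
            else:  # sign change through an exact zero sample
                zer = np.nonzero(seg == 0)[0]
                j = last_idx + (zer[-1] if len(zer) else 0)
            a, b = d2[j], d2[j + 1] if j + 1 < len(d2) else d2[j]
            frac = 0.5 if a == b else a / (a - b)
            crossings.append(t0 + (j + frac) * dt)
        last_sign, last_idx = s, i
    return np.asarray(crossings)


def _dvdt(traj: Trajectory) -> np.ndarray:
    return np.gradient(traj.V, traj.dt)


def segment_phases(
    traj: Trajectory, criteria: SegmentationCriteria = SegmentationCriteria()
) -> PhasePoints:
    """Locate P0..P4 on a trajectory containing a single AP."""
    t, V, dt = traj.t, traj.V, traj.dt
    dvdt = _dvdt(traj)

    # -- peak / AP presence
    ipk = int(np.argmax(V))
    drift_region = dvdt[: max(ipk // 4, 2)]
    drift = float(np.median(drift_region))
    thr = drift + criteria.upstroke_dvdt
    if np.max(dvdt[: ipk + 1], initial=-np.inf) < thr:
        # no quiet pre-stimulus stretch (e.g. the trace starts on the
        # upstroke): fall back to the absolute threshold
        drift, thr = 0.0, criteria.upstroke_dvdt
    if ipk in (0, len(V) - 1) or np.max(dvdt[:ipk + 1], initial=-np.inf) < thr:
        raise SegmentationError(
            "no AP found: dV/dt never exceeds the upstroke threshold "
            f"({thr:.3g} mV/ms)"
        )
    p1 = float(t[ipk])

    # -- P0: last upward crossing of the upstroke threshold before the peak.
    # Crossings caused by the applied-current steps themselves (protocol
    # breakpoints) are stimulus artifacts, not AP features: mask them out.
    pre = dvdt[: ipk + 1].copy()
    if traj.protocol is not None:
        for b in traj.protocol.breakpoints():
            i = int(round((b - t[0]) / dt))
            lo, hi = max(i - 3, 0), min(i + 4, len(pre))
            if lo < hi and lo > 0:
                pre[lo:hi] = pre[lo - 1]
    ups = np.nonzero((pre[:-1] < thr) & (pre[1:] >= thr))[0]
    if len(ups) == 0:
        if pre[0] >= thr:  # trace starts on the upstroke
            ups = np.array([0])
            p0 = float(t[0])
        else:
            raise SegmentationError("no AP found: no upstroke-threshold crossing")
    else:
        j = int(ups[-1])
        frac = (thr - pre[j]) / (pre[j + 1] - pre[j])
        p0 = float(t[j] + frac * dt)
    # baseline: pre-stimulus resting V -- the stretch before dV/dt first
    # leaves the drift band (falls back to V at P0 for stimulus-free traces)
    j0 = int(ups[0])
    baseline = float(np.median(V[: j0 + 1])) if j0 > 0 else float(V[0])

    # -- P2: recovery of dV/dt above the notch-exit level after the dip
    post = dvdt[ipk:]
    below = np.nonzero(post < criteria.notch_exit_dvdt)[0]
    if len(below) == 0:
        # no rapid early-repolarization segment: degenerate notch, put P2
        # one sample after the peak and let epoch merging absorb it
        p2 = float(t[min(ipk + 1, len(t) - 1)])
    else:
        k = below[0]
        # the notch lives on the upper part of the AP: only accept a slope
        # recovery while V is still above halfway between baseline and peak
        vhalf = baseline + 0.5 * (float(V[ipk]) - baseline)
        upper = V[ipk + k :] > vhalf
        rec = np.nonzero((post[k:] >= criteria.notch_exit_dvdt) & upper)[0]
        if len(rec):
            p2 = float(t[ipk + k + rec[0]])
        else:
            # monotone decline (no notch recovery): plateau onset is where
            # the slope first enters the notch-exit band
            p2 = float(t[ipk + k])

    # -- P3: sustained drop of dV/dt below the plateau-exit level
    i2 = int(np.searchsorted(t, p2))
    ns = max(int(round(criteria.sustain_ms / dt)), 1)
    seg = dvdt[i2:]
    under = seg < criteria.plateau_exit_dvdt
    p3 = None
    run = np.convolve(under.astype(int), np.ones(ns, dtype=int), mode="valid")
    hits = np.nonzero(run == ns)[0]
    if len(hits):
        p3 = float(t[i2 + hits[0]])
    if p3 is None or p3 <= p2:
        # slope is already below the exit threshold at P2 (steep plateau):
        # take the onset of the steepest late-repolarization descent
        imin = i2 + 1 + int(np.argmin(dvdt[i2 + 1 :]))
        p3 = float(t[imin]) if t[imin] > p2 else None
    if p3 is None:
        raise SegmentationError("plateau exit (P3) not found; adjust criteria")

    # -- P4: return to baseline, capped at 99% repolarization
    peak = float(V[ipk])
    amp = peak - baseline
    if amp <= 0:
        raise SegmentationError("non-positive AP amplitude")
    i3 = int(np.searchsorted(t, p3))
    lev99 = peak - 0.99 * amp
    p4 = None
    back = np.nonzero(V[i3:] <= baseline + criteria.baseline_return_mv)[0]
    if len(back):
        p4 = float(t[i3 + back[0]])
    c99 = np.nonzero(V[i3:] <= lev99)[0]
    t99 = float(t[i3 + c99[0]]) if len(c99) else None
    if p4 is None:
        p4 = t99
    elif t99 is not None:
        p4 = min(p4, t99)
    if p4 is None:
        raise SegmentationError("V never returns toward baseline (P4 not found)")

    points = {"P0": p0, "P1": p1, "P2": p2, "P3": p3, "P4": p4}
    points.update({k: float(v) for k, v in criteria.explicit.items()})
    return PhasePoints(
        points["P0"], points["P1"], points["P2"], points["P3"], points["P4"],
        baseline=baseline, peak=peak,
    )


def _merge_short(bounds: list[float], min_len: float) -> list[float]:
    """Remove interior breakpoints until every interval >= min_len.

    The shortest offending interval is merged into its shorter neighbour.
    Outer bounds are never removed.
    """
    b = list(bounds)
    while len(b) > 2:
        lens = np.diff(b)
        i = int(np.argmin(lens))
        if lens[i] >= min_len:
            break
        left = lens[i - 1] if i > 0 else np.inf
        right = lens[i + 1] if i + 1 < len(lens) else np.inf
        # drop the breakpoint shared with the shorter neighbour
        drop = i if left <= right else i + 1
        drop = min(max(drop, 1), len(b) - 2)
        del b[drop]
    return b


def build_epochs(
    traj: Trajectory,
    gate: str,
    phases: PhasePoints,
    min_epoch_ms: float = 0.05,
    tol_v: float = 1e-3,
    tol_gate: float = 1e-6,
    smooth_ms: float = 0.005,
) -> EpochSet:
    """Epoch decomposition for one gate over the segmented AP.

    Breakpoints are the phase points, the inflection points of V and of the
    gate's trajectory, and the local extrema of V (so V is monotone inside
    each epoch). Epochs shorter than ``min_epoch_ms`` are merged.
    Tolerances are scaled by the amplitude of the respective series.
    """
    t, dt = traj.t, traj.dt
    V = traj.V
    x = traj.state(gate)
    t0, t4 = phases.p0, phases.p4
    m = (t >= t0) & (t <= t4)
    tv, Vw, xw = t[m], V[m], x[m]

    tolV = tol_v * max(np.ptp(Vw), 1.0)
    tolx = tol_gate * max(np.ptp(xw), 1e-3)
    smooth = max(int(round(smooth_ms / dt)), 1)

    cuts = set()
    for s, tol in ((Vw, tolV), (xw, tolx)):
        for c in second_derivative_sign_changes(s, dt, tol, t0=tv[0], smooth=smooth):
            cuts.add(float(c))
    # local extrema of V: sign changes of dV/dt with hysteresis via the same
    # machinery applied to the first derivative (tolerance in mV/ms, fixed
    # physical scale so epoch sets are grid-independent)
    dv = np.gradient(Vw, dt)
    dv_tol = tolV * 0.01
    sgn = np.where(dv > dv_tol, 1, np.where(dv < -dv_tol, -1, 0))
    last = 0
    for i in np.nonzero(sgn)[0]:
        if last != 0 and sgn[i] != last:
            seg = dv[: i + 1]
            flips = np.nonzero(np.sign(seg[:-1]) * np.sign(seg[1:]) < 0)[0]
            j = flips[-1] if len(flips) else i - 1
            cuts.add(float(tv[0] + (j + 0.5) * dt))
        last = sgn[i]

    epochs: list[Epoch] = []
    for ph in range(4):
        a, b = phases.phase_bounds(ph)
        inner = sorted(c for c in cuts if a + dt < c < b - dt)
        bounds = _merge_short([a] + inner + [b], min_epoch_ms)
        # deduplicate bounds closer than dt
        dedup = [bounds[0]]
        for c in bounds[1:]:
            if c - dedup[-1] > dt:
                dedup.append(c)
        if dedup[-1] != b:
            dedup[-1] = b
        for s, e in zip(dedup[:-1], dedup[1:]):
            vs = float(np.interp(s, t, V))
            ve = float(np.interp(e, t, V))
            seg = Vw[(tv >= s) & (tv <= e)]
            mono = True
            if len(seg) > 2:
                d = np.diff(seg)
                mono = bool(np.all(d >= -tolV * dt) or np.all(d <= tolV * dt))
            epochs.append(Epoch(float(s), float(e), vs, ve, mono, ph))
    return EpochSet(gate, tuple(epochs))


def apd(
    traj: Trajectory,
    fraction: float,
    phases: PhasePoints | None = None,
    criteria: SegmentationCriteria = SegmentationCriteria(),
) -> float:
    """AP duration at ``fraction``% repolarization (ms, measured from P0)."""
    if not (0 < fraction < 100):
        raise ValueError("fraction must be in (0, 100)")
    if phases is None:
        phases = segment_phases(traj, criteria)
    t, V = traj.t, traj.V
    peak, base = phases.peak, phases.baseline
    level = peak - fraction / 100.0 * (peak - base)
    i1 = int(np.searchsorted(t, phases.p1))
    post_t, post_v = t[i1:], V[i1:]
    below = np.nonzero(post_v <= level)[0]
    if len(below) == 0:
        raise SegmentationError(
            f"V never repolarizes to the {fraction}% level ({level:.2f} mV)"
        )
    j = int(below[0])
    if j == 0:
        tc = float(post_t[0])
    else:
        a, b = post_v[j - 1], post_v[j]
        tc = float(post_t[j - 1] + (a - level) / (a - b) * (post_t[j] - post_t[j - 1]))
    return tc - phases.p0


def make_iois(phases: PhasePoints, n: int = 4) -> dict[str, tuple[float, float]]:
    """Split each phase into ``n`` equal sub-intervals, labelled PiIoIj."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out: dict[str, tuple[float, float]] = {}
    for i in range(4):
        a, b = phases.phase_bounds(i)
        edges = np.linspace(a, b, n + 1)
        for j in range(n):
            out[f"P{i}IoI{j + 1}"] = (float(edges[j]), float(edges[j + 1]))
    return out


@dataclass
class RegionSet:
    """Phase points, per-gate epoch sets, IoIs and APD marks for one AP."""

    phases: PhasePoints
    epoch_sets: dict[str, EpochSet]
    iois: dict[str, tuple[float, float]]
    apd_marks: dict[int, float]  # fraction -> duration from P0 (ms)

    def to_json(self, path=None) -> str:
        payload = {
            "phases": self.phases.as_dict(),
            "iois": {k: list(v) for k, v in self.iois.items()},
            "apd": {f"AP{k}": v for k, v in self.apd_marks.items()},
            "epochs": {
                g: [
                    {
                        "t_start": e.t_start, "t_end": e.t_end,
                        "V_start": e.V_start, "V_end": e.V_end,
                        "monotone": e.monotone, "phase": e.phase,
                    }
                    for e in es.epochs
                ]
                for g, es in self.epoch_sets.items()
            },
        }
        s = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s
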