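"""Model-spec files, analysis configuration, and structured outputs.

A model file (YAML or JSON) declares a cell model in the package's
format: gating sigmoids and sum-of-exponential time constants, gated
ohmic channels, ionic concentrations, capacitance, initial state, and an
optional named built-in block of extra dynamics (pumps/Ca2+ handling).
The schema is validated strictly: unknown keys are rejected with their
location.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import __version__
from .core import (
    CellModel,
    ChannelSpec,
    ConfigurationError,
    GateSpec,
    IonConcentrations,
    PhysicalConstants,
)
from .contribution import AnalysisSettings, ContributionTable
from .segment import RegionSet, SegmentationCriteria
from .simulate import SolverOptions, StimulusProtocol, Trajectory

__all__ = [
    "AnalysisConfig",
    "read_model_spec",
    "write_model_spec",
    "write_outputs",
    "resolve_model",
    "builtin_models",
]


# -- extra-dynamics registry ---------------------------------------------

def _extra_dynamics_registry():
    from .ratmodel import (
        RAT_CA_PARAMS,
        RAT_PUMP_PARAMS,
        _rat_extra_currents,
        _rat_non_gating,
    )

    def _toy_readout(view, V, currents, i_density, params, gate_derivs):
        return params["kappa"] * gate_derivs["x"]

    return {
        "rat_ca_handling": {
            "extra_currents": _rat_extra_currents,
            "non_gating_dynamics": _rat_non_gating,
            "default_params": {**RAT_CA_PARAMS, **RAT_PUMP_PARAMS},
        },
        "toy_readout": {
            "voltage_rhs": _toy_readout,
            "default_params": {"kappa": 100.0},
        },
    }


def builtin_models() -> dict:
    """Named model builders available without a spec file."""
    from .fixtures import squid_axon_model, toy_threshold_model
    from .ratmodel import build_rat_model

    return {
        "rat-lv-2021": build_rat_model,
        "squid-axon": squid_axon_model,
        "toy-threshold": lambda: toy_threshold_model(
            tau=2.0, x_inf=0.9, x0=0.0, theta=0.9 * (1 - 1 / 2.718281828459045)
        ),
    }


def resolve_model(ref: str) -> CellModel:
    """A built-in model name, or a path to a model-spec file."""
    reg = builtin_models()
    if ref in reg:
        return reg[ref]()
    p = Path(ref)
    if p.exists():
        return read_model_spec(p)
    raise ConfigurationError(
        f"unknown model {ref!r}: not a built-in ({', '.join(sorted(reg))}) "
        "and no such file"
    )


# -- spec-file schema ----------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class _GateSchema(_Strict):
    name: str
    ss: tuple[float, float]
    tau: list[tuple[float, float, float]]
    driver: str = "V"


class _ChannelSchema(_Strict):
    name: str
    g: float
    gates: list[tuple[str, int]] = []
    ion: str | None = None
    e_fixed: float | None = None

    @model_validator(mode="after")
    def _one_reversal(self):
        if (self.ion is None) == (self.e_fixed is None):
            raise ValueError(f"channel {self.name!r}: give exactly one of ion/e_fixed")
        return self


class _ConcSchema(_Strict):
    external: dict[str, float] = {}
    internal: dict[str, float] = {}
    internal_states: dict[str, str] = {}


class _ConstSchema(_Strict):
    F: float = 96487.0
    T: float = 310.15
    R: float = 8314.0


class _ModelSchema(_Strict):
    name: str = "model"
    capacitance: float
    constants: _ConstSchema = _ConstSchema()
    concentrations: _ConcSchema = _ConcSchema()
    gates: list[_GateSchema]
    channels: list[_ChannelSchema]
    initial_state: dict[str, float]
    extra_dynamics: str | None = None
    params: dict[str, float] = {}


def read_model_spec(path) -> CellModel:
    """Load and validate a model-spec file into a CellModel."""
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text)
    try:
        ms = _ModelSchema.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            "/".join(str(x) for x in e["loc"]) + ": " + e["msg"] for e in exc.errors()
        )
        raise ConfigurationError(f"{path}: invalid model spec ({locs})") from None

    extra_currents = non_gating = None
    params = dict(ms.params)
    if ms.extra_dynamics is not None:
        reg = _extra_dynamics_registry()
        if ms.extra_dynamics not in reg:
            raise ConfigurationError(
                f"{path}: unknown extra_dynamics {ms.extra_dynamics!r} "
                f"(available: {', '.join(sorted(reg))})"
            )
        entry = reg[ms.extra_dynamics]
        extra_currents = entry.get("extra_currents")
        non_gating = entry.get("non_gating_dynamics")
        voltage_rhs = entry.get("voltage_rhs")
        params = {**entry["default_params"], **params}
    else:
        voltage_rhs = None

    return CellModel(
        gates=[GateSpec(g.name, g.ss[0], g.ss[1], tuple(g.tau), g.driver) for g in ms.gates],
        channels=[
            ChannelSpec(c.name, c.g, tuple(c.gates), ion=c.ion, e_fixed=c.e_fixed)
            for c in ms.channels
        ],
        capacitance=ms.capacitance,
        constants=PhysicalConstants(ms.constants.F, ms.constants.T, ms.constants.R),
        concentrations=IonConcentrations(
            external=ms.concentrations.external,
            internal=ms.concentrations.internal,
            internal_states=ms.concentrations.internal_states,
        ),
        state_layout=list(ms.initial_state.keys()),
        initial_state=ms.initial_state,
        extra_currents=extra_currents,
        non_gating_dynamics=non_gating,
        voltage_rhs=voltage_rhs,
        params=params,
        name=ms.name,
    )


def write_model_spec(model: CellModel, path, extra_dynamics: str | None = None) -> None:
    """Serialize a CellModel to the spec-file format (YAML).

    ``extra_dynamics`` must name a registered built-in when the model uses
    hooks; hook code itself is not serializable.
    """
    if (
        model.extra_currents or model.non_gating_dynamics or model.voltage_rhs
    ) and extra_dynamics is None:
        raise ConfigurationError(
            "model has extra dynamics; pass the registered built-in name"
        )
    doc = {
        "name": model.name,
        "capacitance": model.capacitance,
        "constants": {
            "F": model.constants.F, "T": model.constants.T, "R": model.constants.R,
        },
        "concentrations": {
            "external": dict(model.concentrations.external),
            "internal": dict(model.concentrations.internal),
            "internal_states": dict(model.concentrations.internal_states),
        },
        "gates": [
            {
                "name": g.name, "ss": [g.ss_a1, g.ss_a2],
                "tau": [list(t) for t in g.tau_terms],
                **({"driver": g.driver} if g.driver != "V" else {}),
            }
            for g in model.gates
        ],
        "channels": [
            {
                "name": c.name, "g": c.conductance,
                "gates": [list(gp) for gp in c.gate_powers],
                **({"ion": c.ion} if c.ion is not None else {"e_fixed": c.e_fixed}),
            }
            for c in model.channels
        ],
        "initial_state": {k: float(v) for k, v in model.initial_state.items()},
    }
    if extra_dynamics is not None:
        doc["extra_dynamics"] = extra_dynamics
        doc["params"] = {
            k: float(v) for k, v in model.params.items()
            if isinstance(v, (int, float))
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# -- analysis configuration ----------------------------------------------

class _ProtocolSchema(_Strict):
    amplitude: float = 528.0
    onset: float = 0.0
    duration: float | None = None
    total_time: float = 5000.0
    mode: Literal["constant", "pulse"] = "constant"


class _SolverSchema(_Strict):
    method: str = "BDF"
    rtol: float = 1e-8
    atol: float = 1e-10
    output_dt: float = 0.001
    max_step: float | None = None


class _CriteriaSchema(_Strict):
    upstroke_dvdt: float = 1.0
    notch_exit_dvdt: float = -1.0
    plateau_exit_dvdt: float = -0.5
    sustain_ms: float = 0.5
    baseline_return_mv: float = 2.0
    explicit: dict[str, float] = {}


class AnalysisConfig(_Strict):
    """Schema-validated configuration of a full contribution analysis."""

    model: str = "rat-lv-2021"
    capacitance: float | None = None
    protocol: _ProtocolSchema = _ProtocolSchema()
    solver: _SolverSchema = _SolverSchema()
    criteria: _CriteriaSchema = _CriteriaSchema()
    delta: float = 0.10
    t_end: float | None = 250.0
    n_ioi: int = 4
    apd_fractions: list[int] = [20, 50, 90]
    min_epoch_ms: float = 0.05
    gates: list[str] | None = None
    regions: list[Literal["phases", "iois", "apd"]] = ["phases", "iois", "apd"]

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            return cls.model_validate(raw)
        except ValidationError as exc:
            locs = "; ".join(
                "/".join(str(x) for x in e["loc"]) + ": " + e["msg"]
                for e in exc.errors()
            )
            raise ConfigurationError(f"{path}: invalid config ({locs})") from None

    def build(self):
        """(model, protocol, AnalysisSettings) ready for run_full_analysis."""
        import numpy as np

        model = resolve_model(self.model)
        protocol = StimulusProtocol(
            amplitude=self.protocol.amplitude,
            onset=self.protocol.onset,
            duration=self.protocol.duration,
            total_time=self.protocol.total_time,
            mode=self.protocol.mode,
        )
        solver = SolverOptions(
            method=self.solver.method,
            rtol=self.solver.rtol,
            atol=self.solver.atol,
            output_dt=self.solver.output_dt,
            max_step=self.solver.max_step if self.solver.max_step else np.inf,
        )
        criteria = SegmentationCriteria(
            upstroke_dvdt=self.criteria.upstroke_dvdt,
            notch_exit_dvdt=self.criteria.notch_exit_dvdt,
            plateau_exit_dvdt=self.criteria.plateau_exit_dvdt,
            sustain_ms=self.criteria.sustain_ms,
            baseline_return_mv=self.criteria.baseline_return_mv,
            explicit=dict(self.criteria.explicit),
        )
        settings = AnalysisSettings(
            delta=self.delta,
            t_end=self.t_end,
            n_ioi=self.n_ioi,
            apd_fractions=tuple(self.apd_fractions),
            min_epoch_ms=self.min_epoch_ms,
            gates=tuple(self.gates) if self.gates else None,
            solver=solver,
            criteria=criteria,
            regions=tuple(self.regions),
        )
        return model, protocol, settings


# -- outputs -------------------------------------------------------------

def _model_hash(model: CellModel) -> str:
    payload = json.dumps(
        {
            "name": model.name,
            "gates": [
                (g.name, g.ss_a1, g.ss_a2, g.tau_terms, g.driver) for g in model.gates
            ],
            "channels": [
                (c.name, c.conductance, c.gate_powers, c.ion, c.e_fixed)
                for c in model.channels
            ],
            "capacitance": model.capacitance,
            "initial": model.initial_state,
            "params": {
                k: v for k, v in sorted(model.params.items())
                if isinstance(v, (int, float))
            },
        },
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_outputs(
    table: ContributionTable | None,
    regions: RegionSet | None,
    traj: Trajectory | None,
    outdir,
    model: CellModel | None = None,
    config: AnalysisConfig | None = None,
    model_provenance: str | None = None,
) -> dict[str, str]:
    """Write trajectory CSV, regions JSON, contribution CSV/JSON and a run
    manifest into ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    if traj is not None:
        traj.to_csv(outdir / "trajectory.csv")
        written["trajectory"] = str(outdir / "trajectory.csv")
    if regions is not None:
        regions.to_json(outdir / "regions.json")
        written["regions"] = str(outdir / "regions.json")
    if table is not None:
        table.to_csv(outdir / "contributions.csv")
        written["contributions"] = str(outdir / "contributions.csv")
        with open(outdir / "contributions.json", "w") as fh:
            json.dump(table.to_json(), fh, indent=2)
        written["contributions_json"] = str(outdir / "contributions.json")
        table.clipped_matrix().to_csv(outdir / "heatmap.csv", index_label="gate")
        written["heatmap"] = str(outdir / "heatmap.csv")

    manifest = {
        "software": {"name": "apcontrib", "version": __version__},
        "model": None if model is None else {
            "name": model.name,
            "hash": _model_hash(model),
            "n_states": model.n_states,
            "capacitance_pF": model.capacitance,
        },
        "config": None if config is None else config.model_dump(),
        "model_provenance": model_provenance,
        "outputs": written,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    written["manifest"] = str(outdir / "manifest.json")
    return written
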