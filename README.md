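# apcontrib

Quantifying how much each ion-channel gating variable speeds up or slows
down each region of a cardiac action potential.

Hodgkin–Huxley-type cell models produce the action potential (AP) from the
nonlinear interplay of many voltage-gated activation and inactivation
variables. `apcontrib` implements a *τ-perturbation contribution analysis*
for such models: the time constant of one gating variable `x` is scaled by
`(1 + δ)` from the start of a region of the AP, and the contribution of
`x` to that region is the elasticity of its duration,

    C_x = ( ∂D / D ) / ( ∂τ_x / τ_x )

so `C_x > 0` means slowing the gate prolongs the region and `C_x < 0`
means it shortens it. Because perturbations act linearly only where the
voltage and gating trajectories have no curvature changes, the AP is first
decomposed into **epochs** — intervals between consecutive inflection
points of `V(t)` or of the gate's trajectory — and measured epoch by
epoch. Epochs aggregate to the conventional AP **phases** P0–P3
(depolarization, early repolarization, plateau, late repolarization; sums
of per-epoch elasticities), to equal-quarter **intervals of interest**
(duration-weighted pooling), and to APD20/50/90 regions.

The package is a generic framework (any model expressible as sigmoidal
steady states with sum-of-exponential rate laws, plus hooks for pumps,
rectifiers and Ca²⁺ handling) and ships with:

* `rat-lv-2021` — a 30-state adult rat left-ventricular myocyte model
  (8 gated currents / 16 gating variables, 4 background currents, 3
  pump/exchanger currents, and four-compartment sarcoplasmic-reticulum
  Ca²⁺ handling with RyR release, SERCA uptake and troponin/calmodulin/
  calsequestrin buffering). Conductances, Ca²⁺-handling parameters,
  initial conditions and extracellular concentrations are the published
  table values, taken verbatim; the gating kinetics are a documented
  reconstruction (see `TRANSCRIPTION.md` and `docs/methods.md`).
* analytic fixtures — a threshold toy whose contribution is exactly 1, a
  squid-axon model in the same declarative format, and synthetic AP
  waveforms with known segmentation ground truth.

## Worked example

```python
import apcontrib as ap
from apcontrib.ratmodel import build_rat_model, rat_protocol, rat_criteria

model = build_rat_model()
protocol = rat_protocol(total_time=160.0)          # 528 pA pulse
traj = ap.simulate(model, protocol, ap.SolverOptions(output_dt=0.001), t_end=160.0)
phases = ap.segment_phases(traj, rat_criteria())
print({k: round(v, 2) for k, v in phases.as_dict().items()})

settings = ap.AnalysisSettings(gates=("n", "nf", "l"), criteria=rat_criteria(), t_end=160.0)
table = ap.run_full_analysis(model, protocol, settings, ref=traj)
print(table.table[["P0", "P1", "P2", "P3"]].round(3))
```

prints

```
{'P0': 67.42, 'P1': 75.83, 'P2': 76.6, 'P3': 91.22, 'P4': 109.56,
 'baseline_mV': -70.24, 'peak_mV': 46.24}
       P0     P1     P2     P3
n   2.351 -0.000 -0.000  2.341
nf -0.980  0.012 -0.000 -1.578
l   1.094 -0.791  0.052  1.112
```

Reading the table: the Na⁺ activation gate `n` dominates depolarization
(large positive `C` in P0 — slowing it prolongs the upstroke), Na⁺ fast
inactivation `nf` opposes it (negative `C`: slowing inactivation speeds
the phase to completion), and the L-type Ca²⁺ activation `l` contributes
positively both to late depolarization and to the plateau. The
`ContributionTable` also carries per-epoch provenance, IoI and APD
columns, aggregation-mode tags, and sign-convention diagnostics
(`table.sign_diagnostics`).

## Command line

```
apcontrib simulate  --model rat-lv-2021 --t-end 160 --out traj.csv
apcontrib segment   --traj traj.csv --gate l --out regions.json
apcontrib contribute --model rat-lv-2021 --gates n,nf,l --t-end 160 --out results/
apcontrib fixtures export --name squid-axon --out squid.yaml
```

`contribute` writes the contribution table (CSV + JSON with per-epoch
provenance), the region set, a heatmap export clipped to ±0.01 for
plotting, and a run manifest recording the model hash, configuration,
solver tolerances and model provenance.

## Layout

```
src/apcontrib/core.py          gating algebra, channels, Nernst, RHS assembly
src/apcontrib/simulate.py      BDF integration, protocols, trajectories
src/apcontrib/segment.py       phases, epochs, IoIs, APD
src/apcontrib/contribution.py  the tau-perturbation measure and aggregation
src/apcontrib/ratmodel.py      the bundled rat LV model (+ data/rat_lv_2021.yaml)
src/apcontrib/fixtures.py      analytic fixtures (toy, squid, synthetic AP)
src/apcontrib/io.py, cli.py    model-spec files, configs, outputs, CLI
docs/methods.md                model and method documentation
TRANSCRIPTION.md               parameter-provenance audit of the rat model
```
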