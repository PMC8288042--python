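# Methods

## The contribution measure

For a conductance-based membrane model with gating variables relaxing as
`dx/dt = (x∞(u) − x)/τ_x(u)`, the contribution of gate `x` to a region
`[t₀, t₁]` of the action potential is the elasticity of the region's
duration with respect to the gate's time constant:

    C = ((D′ − D)/D) / δ

where `D = t₁ − t₀` is the reference duration and `D′` is measured by
re-integrating the model from the *reference state at t₀* with `τ_x(u)`
multiplied by `(1 + δ)` everywhere, stopping when `V` crosses the
reference end voltage `V(t₁)` in the reference direction of change.
`C > 0`: slowing the gate prolongs the region. The default `δ` is 0.10 —
large enough that the duration change is far above solver noise, small
enough to stay near the linear regime (the toy fixture, where `D ∝ τ`
exactly, gives `C = 1` for any `δ`).

Measurement mechanics and edge cases:

* **Perturbation semantics.** Multiplicative scaling of `τ_x(u)` for the
  whole perturbed integration — a slowed rate law, not a one-time state
  kick. Each region's run restarts from the unperturbed reference state
  at the region start; effects never carry over between regions.
* **Stopping rule.** The end event is the crossing of the reference end
  voltage in the reference direction. This is well-posed because regions
  are constructed with `V` monotone inside them (voltage extrema are
  always region boundaries). `δ = 0` short-circuits to the reference
  duration exactly.
* **Reversal fallback.** Some perturbations prevent the end level from
  ever being reached — e.g. slowing Na⁺ activation lowers the AP peak,
  so the epoch ending exactly at the peak voltage cannot terminate by
  crossing. If the perturbed trajectory reverses direction (beyond a
  guard of 2% of the mean reference slope) before reaching the level,
  the duration is taken at the extremum — the closest approach — and the
  result is flagged `clipped`.
* **Flat regions.** If the reference voltage change over a region is
  below 1 nV the region carries no measurable end level; the result is
  flagged `degenerate` and its `C` is 0.
* **Unbounded effects.** If neither the level crossing nor a reversal
  occurs within 50× the reference duration, the cell errors out; errors
  are recorded per (gate, region) and the analysis continues.

## Regions: epochs, phases, IoIs, APD

Epoch boundaries are: the phase points, the zero crossings of `d²V/dt²`
and of `d²x/dt²` for the gate under analysis, and the local extrema of
`V`. Second derivatives are central differences with hysteresis: a zero
crossing counts only between excursions beyond `±tol`, with
`tol = 10⁻³ × amplitude` for `V` (mV/ms²) and `10⁻⁶ × amplitude` for
gates — the plateau is nearly flat and raw second derivatives chatter
there. The second derivative is pre-smoothed over a 0.005 ms window and
the extremum hysteresis uses a fixed mV/ms scale, both in physical units
so the epoch set is independent of the output grid (this is what makes
the dt = 0.001 vs 0.0001 ms analyses agree to < 0.01 in every phase-level
value). Epochs shorter than 0.05 ms are merged into their shorter
neighbour, phase boundaries never move.

Phase points P0–P4 are detected on `dV/dt` with overridable criteria:

* P0 — last upward crossing, before the peak, of the upstroke threshold
  (default 1 mV/ms above the pre-stimulus drift; crossings caused by
  applied-current steps are masked out as stimulus artifacts),
* P1 — the voltage maximum,
* P2 — recovery of `dV/dt` above the notch-exit level (−1 mV/ms) while V
  is still on the upper half of the AP; for monotone-decline APs, entry
  into that band,
* P3 — sustained drop below the plateau-exit level (−0.5 mV/ms default;
  −7.5 for the bundled rat AP, whose plateau itself declines at
  −2…−5 mV/ms), falling back to the steepest-descent point,
* P4 — return of V to within 2 mV of the pre-stimulus baseline, capped
  at 99% repolarization.

Explicit user times always win; phases are inherently user-dependent
quantities, and the defaults are calibrated, not canonical.

Aggregation uses two published forms deliberately kept distinct: phase
totals are **sums of per-epoch elasticities** `Σₖ Cₖ`, while IoIs (equal
quarters of each phase) and APD20/50/90 regions are **duration-pooled**,
`C = (Σₖ ΔDₖ / Σₖ Dₖ)/δ`. A sum of elasticities can legitimately exceed 1
when several consecutive epochs are each rate-limited by the same gate;
pooling cannot. Epochs straddling an IoI boundary are cut there and the
pieces pooled (sub-intervals of an epoch keep `V` monotone, so the
measurement stays well-posed). Every aggregate is traceable to its
epoch-level results in the output JSON.

The sign convention is implemented as a rule set and checked as a
diagnostic on every analysis: a gate moving in the same direction as `V`
through a channel with positive reversal potential contributes
positively; opposite motion gives a negative sign; both flip for
negative-reversal (K⁺) channels.

## Numerical choices

* Integrator: SciPy BDF (variable-order implicit multistep), the
  standard family for these stiff systems; rtol 1e-8 / atol 1e-10 by
  default — contribution values are small ratios of durations and the
  solver error must sit well below them. Halving the tolerances changes
  the rat AP by < 0.01 mV (tested).
* Analytic-fixture tests run at rtol 1e-12 / atol 1e-14 so the
  1e-6…1e-9 oracle bounds are not solver-limited.
* Output grids: 0.001 ms default, 0.0001 ms for the step-size-stability
  check. Dense solver output backs state look-ups between grid points.
* Event location uses the solver's root finding on the event functions;
  exponent arguments are clamped to ±500 so Newton iterations at extreme
  voltages never produce NaN.
* The analysis window for the bundled model is 160 ms — it covers the
  stimulus, the full AP (P4 ≈ 110 ms) and a post-AP margin; the tests and
  the acceptance script use gate subsets where only specific gates are
  probed. Both are the package's own problem-size choices.

## The bundled rat model

`TRANSCRIPTION.md` is the line-by-line provenance audit. In short: all
printed numbers (conductances, Ca²⁺-handling parameters, initial state,
extracellular concentrations, stimulus amplitude, physical constants)
are verbatim; the gating kinetics, pump formulations, I_K1 rectification
and C_m are reconstructed, because the published coefficient set was not
available. Two principles anchored the reconstruction:

1. every gate's sigmoid offset is solved from its printed initial value
   at the printed −72 mV rest, so the printed state is an exact gating
   equilibrium — the printed initial conditions are data, and this uses
   all 16 of them;
2. slopes and time constants start from classic rat-LV kinetics and were
   calibrated **only against published AP landmarks** (peak band
   30–50 mV, phase times 67.44/70.92/76/90.76/110 ms, quiescent rest) —
   never against published contribution values, which remain genuine
   predictions of the reconstruction.

What the reconstruction reproduces: a stable rest near −72 mV with no
spontaneous firing; a single AP per stimulus with peak +46 mV and
APD90 ≈ 40 ms; phase landmarks P0/P2/P3/P4 within 1 ms of the published
times; the phase-0 contribution sign structure (n: +, nf: −, ns: −, l: +,
with n dominant); the published nf phase-0 magnitude (−0.98 vs −0.99);
positive plateau contributions of the L-type activation and the slow
delayed rectifier; and < 0.01 step-size stability of phase-level values.

Known deviations, all consequences of the missing kinetics:

* the AP maximum is the apex of a Ca²⁺-carried dome ~5 ms after the Na⁺
  spike, so P1 sits at ~75.8 ms instead of 70.92 and the detected
  phase 1 is short;
* with the printed s = 0.1776 treated as resting equilibrium, `s∞(V)`
  exceeds `s` throughout the AP, so the slow delayed rectifier always
  activates and its phase-3 contribution is positive, where the
  published value (−0.12) requires deactivation;
* contribution magnitudes other than nf/P0 differ from the published
  ones — per-epoch elasticities are sensitive to the exact τ values;
* a sustained 528 pA step holds the reconstructed membrane depolarized
  after the AP, so the bundled protocol is a 10 ms pulse (amplitude
  verbatim, onset calibrated so P0 = 67.44 ms);
* the printed RyR rates imply a standing SR leak and a high resting
  subspace Ca²⁺ (~0.06 mM); taken verbatim, with the Ca²⁺-dependent
  inactivation half-point placed above it (0.9 mM).

Run manifests written by `apcontrib contribute` carry a
`model_provenance` field stating the reconstruction, so downstream
consumers can tell these results from ones obtained with transcribed
kinetics.

## Fixtures, and what passing tests show

* **Toy threshold model** — one gate with fixed `x∞` and `τ`, voltage a
  linear readout of the gate. The event time is
  `τ·ln((x∞−x₀)/(x∞−θ))`, exactly proportional to `τ`, so `C = 1` for
  every `δ` and a decoupled second gate gives `C = 0`. This validates
  the whole measurement chain (state hand-off, event stopping,
  normalization) against closed forms at the 1e-9 level.
* **Squid axon** — the classic 4-state excitable model converted to the
  declarative format. The conversion is approximate and deliberately
  documented as such: positive sums of exponentials are log-convex in V,
  and the saturating inactivation rate is not, so its best fit deviates
  up to ~55% at the depolarized extreme (~16% for the activation rates).
  The fixture demonstrates generality (the analysis runs unchanged on a
  neuronal AP and finds the Na⁺-activation-dominated upstroke), not
  quantitative squid physiology.
* **Synthetic AP waveforms** — piecewise half-cosine traces with
  analytically known landmark times, used to verify segmentation
  (including noise-robustness with an explicit seed).

Passing tests therefore establish the *method's* correctness on models
with known answers and the *bundled model's* agreement with the published
morphology and sign structure. They do not establish that the bundled
model reproduces real rat-ventricular data beyond those calibrated
features, and the method by construction cannot measure time-independent
currents (pumps, exchangers, background leaks): a perturbation target
`τ` must exist.

## Limitations

* Single-AP analysis; no restitution or multi-beat protocols.
* Phase-point defaults are calibrated to the bundled AP; other models
  will generally need criterion overrides (they are all exposed).
* The summed phase aggregation is epoch-count sensitive by design (it is
  the published formulation); when comparing across models or grids,
  prefer the pooled values, which are stable under epoch refinement.
* Ion concentrations drift slowly at rest (the printed background
  conductances are large); over the 160 ms analysis window the drift is
  negligible, but the model is not a long-horizon homeostasis model.
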