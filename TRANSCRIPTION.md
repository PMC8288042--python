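# Parameter provenance audit — `rat-lv-2021`

Every equation and number in `src/apcontrib/ratmodel.py`, classified by
source. "Verbatim" means copied digit-for-digit from the published
parameter tables of the source model; "reconstructed" means the published
value or functional form was not available and the entry is this
package's own, documented choice.

## Verbatim (published tables)

| Block | Items | Code location |
|---|---|---|
| Channel conductances (nS/pF) | gNa 1.0044e3, gt 6.4718, ghf 7.7282, gK1 6, gKr 5.7017, gCaL 6.2894, gKs 6.4916, gCaT 1.5854, gClb 1.5278, gBNa 0.0326, gBK 0.05, gBCa 0.0025 | `RAT_CONDUCTANCES` |
| RyR rates | ka± 5.78e6 / 0.5128, kb± 2.1586e7 / 3.4472, kc± 0.0513 / 0.0062, v1 10.5921 | `RAT_CA_PARAMS` |
| SERCA | Kfb 9.6176e-4, Krb 28.1467, Ksr 2.3974, Nfb 1.2, Nrb 1, vmaxf 4e-5, vmaxr 9e-4 | `RAT_CA_PARAMS` |
| Transfer time constants | τtr 0.9258 ms, τxfer 0.5234 ms | `RAT_CA_PARAMS` |
| Buffers | khtrpn± , kltrpn±, HTRPNtot 0.14, LTRPNtot 0.07, CMDNtot 0.05, CSQNtot 15, KmCMDN 0.00238, KmCSQN 0.8 | `RAT_CA_PARAMS` |
| EGTA | kEGTA− 0.00015, EGTAtot 10 — carried but disabled (experimental chelator, not part of the current-clamp membrane model) | `RAT_CA_PARAMS` |
| Geometry | Vmyo 9.36, VJSR 0.056, Vss 0.0012, VNSR 0.504 pL; Acap 0.8004 (carried, unused — see below) | `RAT_CA_PARAMS` |
| Physical constants | F 96,487 C/mol, T 310.15 K, R 8314 mJ/(mol·K) | `PhysicalConstants` |
| Initial state (30 entries) | V −72 … LTRPNCa 0.00516, exactly as printed | `RAT_INITIAL_STATE` |
| Extracellular | Na 140, K 5.4, Ca 1.5, Cl 140 mM | `RAT_EXTRACELLULAR` |
| Stimulus amplitude | 528 pA | `rat_protocol` |

Notes on verbatim entries taken *as printed* even where they look
surprising:

* The initial RyR occupancies PC1 = PC2 = 0.634 sum (with PO1, PO2) to
  ≈ 1.268, not 1. They are used verbatim; the four-state scheme conserves
  whatever total it starts with, so no renormalization is applied.
* kc⁺/kc⁻ = 0.0513/0.0062 ms⁻¹ put a visible standing RyR leak at rest;
  together with v1 = 10.5921 this drives the subspace Ca²⁺ to a high
  resting value (~0.06 mM). Taken verbatim; consequences are documented
  in `docs/methods.md`.
* Krb = 28.1467 mM is an order of magnitude above the classic
  four-compartment value; verbatim.
* The prose description of the source model counts 32 differential
  equations, but the printed initial-condition table lists 30 state
  variables; this implementation has the 30 printed states.

## Reconstructed (published values unavailable)

| Block | Choice | Rationale / calibration data |
|---|---|---|
| Gating sigmoid offsets (a2) | solved exactly from each gate's printed initial value at the printed resting −72 mV | makes the printed initial state an exact gating equilibrium |
| Gating slopes and time constants | `GATE_KINETICS`: slope factors and (mostly constant) τ values | started from classic rat-LV kinetics (Pandit et al. 2001 lineage), calibrated against the published AP landmarks only: peak in 30–50 mV, phase times 67.44 / 70.92 / 76 / 90.76 / 110 ms; never against contribution values |
| Ca²⁺-dependent inactivation | sigmoid in subspace Ca²⁺, slope 5 mM⁻¹, τ 20 ms, offset solved from the printed initial value | half-inactivation ≈ 0.9 mM subspace Ca²⁺ |
| Gate powers | n³·nf·ns (Na), l·lf·ls·cdi (CaL), ct³·cti (CaT), kt·ktf·kts (Ito), r·ri (Kr), s² (Ks) | classic stoichiometries; ct³ and s² also required for a stationary rest with the printed conductances |
| Ca²⁺-handling equation forms | Winslow et al. 1999 four-compartment topology (RyR 4-state, SERCA forward/reverse, rapid-buffer closure) with the verbatim rates above | the printed parameter names map one-to-one onto this scheme |
| I_NaK, I_NaCa, I_CaP | Pandit-2001-style formulations; magnitudes (`RAT_PUMP_PARAMS`) balanced for a stationary −72 mV rest | no pump parameters are printed |
| I_K1 rectification | gK1 · (V−EK) / (1 + exp((V−EK−14)/8.5)) | balanced so the printed gClb/gK1 pair gives a stable rest at −72 mV and a repolarizing phase 3 |
| C_m = 80 pF | within the adult rat LV range; chosen so the printed 528 pA stimulus is suprathreshold | not printed anywhere available |
| Stimulus time course | 10 ms pulse, onset 58.05 ms | amplitude verbatim; onset calibrated so the detected P0 = 67.44 ms; a sustained step holds the reconstructed membrane depolarized after the AP (no P4), so the pulse form is used |
| Current→flux conversion | dC/dt = I[pA]·C_m/(z·F·V[pL]) per compartment | dimensionally closed without an area factor, so Acap is carried but unused |

The reconstruction reproduces: stable rest near the printed −72 mV,
single AP per stimulus, peak 46 mV (printed band 30–50), phase landmarks
P0/P2/P3/P4 within 1 ms of the published times, the published phase-0
contribution sign triple (n +, nf −, ns −) and the published nf phase-0
magnitude (−0.98 vs −0.99). Known deviations are listed in
`docs/methods.md`.
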