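name: rat-lv-2021
capacitance: 80.0
constants:
  F: 96487.0
  T: 310.15
  R: 8314.0
concentrations:
  external:
    Na: 140.0
    K: 5.4
    Ca: 1.5
    Cl: 140.0
  internal: {}
  internal_states:
    Na: Nai
    K: Ki
    Ca: Cai
    Cl: Cli
gates:
- name: n
  ss:
  - -0.2222222222222222
  - -10.507340122772668
  tau:
  - - 0.7142857142857143
    - 0.0
    - 0.0
- name: nf
  ss:
  - 0.2
  - 13.691814942075514
  tau:
  - - 1.0
    - 0.0
    - 0.0
- name: ns
  ss:
  - 0.2
  - 13.691814942075514
  tau:
  - - 0.0625
    - 0.0
    - 0.0
- name: l
  ss:
  - -0.2
  - -1.3264288867673084
  tau:
  - - 0.35714285714285715
    - 0.0
    - 0.0
- name: lf
  ss:
  - 0.14285714285714285
  - 5.690594435579701
  tau:
  - - 0.038461538461538464
    - 0.0
    - 0.0
- name: ls
  ss:
  - 0.13333333333333333
  - 5.004880149865416
  tau:
  - - 0.0125
    - 0.0
    - 0.0
- name: kt
  ss:
  - -0.1111111111111111
  - -1.8362842738391105
  tau:
  - - 0.7142857142857143
    - 0.0
    - 0.0
- name: ktf
  ss:
  - 0.16666666666666666
  - 8.108179701889375
  tau:
  - - 0.2857142857142857
    - 0.0
    - 0.0
- name: kts
  ss:
  - 0.16666666666666666
  - 11.424635855096438
  tau:
  - - 0.016666666666666666
    - 0.0
    - 0.0
- name: r
  ss:
  - -0.125
  - -8.449291296515485
  tau:
  - - 0.02
    - 0.0
    - 0.0
- name: ri
  ss:
  - 0.1
  - 9.39722457733622
  tau:
  - - 0.3333333333333333
    - 0.0
    - 0.0
- name: s
  ss:
  - -0.03333333333333333
  - -0.867306935857169
  tau:
  - - 0.004
    - 0.0
    - 0.0
- name: y
  ss:
  - 0.125
  - 14.651486171157481
  tau:
  - - 0.0025
    - 0.0
    - 0.0
- name: ct
  ss:
  - -0.16666666666666666
  - -9.674093472472181
  tau:
  - - 0.6666666666666666
    - 0.0
    - 0.0
- name: cti
  ss:
  - 0.15384615384615385
  - 13.505760044606324
  tau:
  - - 0.1111111111111111
    - 0.0
    - 0.0
- name: Cai_gate
  ss:
  - 5.0
  - -4.595556710734583
  tau:
  - - 0.05
    - 0.0
    - 0.0
  driver: Cass
channels:
- name: Na
  g: 1004.4
  gates:
  - - n
    - 3
  - - nf
    - 1
  - - ns
    - 1
  ion: Na
- name: CaL
  g: 6.2894
  gates:
  - - l
    - 1
  - - lf
    - 1
  - - ls
    - 1
  - - Cai_gate
    - 1
  ion: Ca
- name: CaT
  g: 1.5854
  gates:
  - - ct
    - 3
  - - cti
    - 1
  ion: Ca
- name: t0
  g: 6.4718
  gates:
  - - kt
    - 1
  - - ktf
    - 1
  - - kts
    - 1
  ion: K
- name: Kr
  g: 5.7017
  gates:
  - - r
    - 1
  - - ri
    - 1
  ion: K
- name: Ks
  g: 6.4916
  gates:
  - - s
    - 2
  ion: K
- name: BNa
  g: 0.0326
  gates: []
  ion: Na
- name: BK
  g: 0.05
  gates: []
  ion: K
- name: BCa
  g: 0.0025
  gates: []
  ion: Ca
- name: Clb
  g: 1.5278
  gates: []
  ion: Cl
initial_state:
  V: -72.0
  n: 0.0041
  nf: 0.67
  ns: 0.67
  l: 2.1e-06
  lf: 0.99
  ls: 0.99
  Cai_gate: 0.99
  kt: 0.0021
  ktf: 0.98
  kts: 0.64
  r: 0.3657
  ri: 0.1
  s: 0.1776
  y: 0.0035
  ct: 0.089
  cti: 0.081
  Nai: 10.73519
  Ki: 139.275
  Cai: 7.9e-05
  Cli: 30.03
  Cass: 8.737212e-05
  CaJSR: 0.06607948
  CaNSR: 0.06600742
  PC1: 0.634
  PO1: 0.0004327
  PO2: 6.06e-10
  PC2: 0.634
  HTRPNCa: 0.139
  LTRPNCa: 0.00516
extra_dynamics: rat_ca_handling
params:
  ka_plus: 5780000.0
  ka_minus: 0.5128
  kb_plus: 21586000.0
  kb_minus: 3.4472
  kc_plus: 0.0513
  kc_minus: 0.0062
  v1: 10.5921
  Kfb: 0.00096176
  Krb: 28.1467
  Ksr: 2.3974
  Nfb: 1.2
  Nrb: 1.0
  vmaxf: 4.0e-05
  vmaxr: 0.0009
  tau_tr: 0.9258
  tau_xfer: 0.5234
  khtrpn_plus: 43.1286
  khtrpn_minus: 0.00071033
  kltrpn_plus: 0.0969
  kltrpn_minus: 0.0013
  HTRPNtot: 0.14
  LTRPNtot: 0.07
  CMDNtot: 0.05
  CSQNtot: 15.0
  KmCMDN: 0.00238
  KmCSQN: 0.8
  kEGTA_minus: 0.00015
  EGTAtot: 10.0
  Vmyo: 9.36
  VJSR: 0.056
  Vss: 0.0012
  VNSR: 0.504
  Acap: 0.8004
  INaK_max: 0.88
  Km_Nai: 10.0
  Km_Ko: 1.5
  kNaCa: 2000.0
  KmNa: 87.5
  KmCa: 1.38
  ksat: 0.1
  eta: 0.35
  ICaP_max: 0.08
  Km_CaP: 0.0005
  fNa_f: 0.2
  K1_half: 14.0
  K1_slope: 8.5
  gK1: 6.0
  ghf: 7.7282
  Cm: 80.0
  F: 96487.0
  R: 8314.0
  T: 310.15
  Ko: 5.4
  Nao: 140.0
  Cao: 1.5
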