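# Parameter set for the 3-D lamellar flux-curve family.
# Same reduced model and printed constants as params_default.yaml; the
# calibrated operating point differs: the surrogate kinase runs at full
# mass-action strength (its ATP->ADP cycling sustains the flux plateau of
# detached cristae), ionic fractions are equal on both membrane sides, the
# translocase works in its ADP-sensitive regime, and diffusivity is at the
# dilute-solution scale. Calibrated to the crista-class contrast: detached
# plateau ~0.6 J/JMAX, narrow-vs-wide CJ ordering, and Rule-of-2
# consistency of trans-CJ addition with CJ widening.
units:
  velocities: molecules/ms/um^2
  binding_constants: mM
  potentials: mV
  diffusivities: um^2/ms
  rates: 1/ms or 1/(mM ms)
parameters:
  V_ANT: 780.0
  V_AS: 287.0
  K_ADP: 0.18
  K_ATP: 4.8
  K_Pi: 1.0
  K_Ca_ATP: 1.65e-4
  K_V_ATP: 131.4
  psi_m: 172.0
  f_P: 0.5
  T: 310.0
  f_ADP3_m: 0.45
  f_ADP3_e: 0.45
  f_ATP4_m: 0.45
  f_ATP4_e: 0.45
  Pi_m: 6.0
  Pi_e: 2.5
  Ca_m: 2.0e-4
  k_f: 0.009
  k_r: 1.0
  kinase_scale: 1.0
  D_ADP: 0.25
  D_ATP: 0.25
  as_flat_denominator: false
provenance:
  printed: [psi_m, f_P, k_f, k_r]
  calibrated: [V_ANT, V_AS, K_ADP, K_ATP, K_Pi, K_Ca_ATP, K_V_ATP, Pi_m,
               Pi_e, Ca_m, D_ADP, D_ATP, kinase_scale]
  notes: >
    Companion to params_default.yaml for the 3-D crista-junction width and
    census-scoring experiments; see docs/methods.md for the two-regime
    discussion.
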