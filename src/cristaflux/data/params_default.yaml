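# Default kinetic parameter set for the reduced metabolic model.
# Provenance "printed": value stated directly in the source model conditions.
# Provenance "calibrated": fixed by the documented calibration protocol
# (crista-free max flux ~100 molecules/ms/um^2, matrix [ADP] window
# 0.18-0.37 mM over the condition grid, gradient steepness k in 1-3.7 1/um).
units:
  velocities: molecules/ms/um^2
  binding_constants: mM
  potentials: mV
  diffusivities: um^2/ms
  rates: 1/ms or 1/(mM ms)
parameters:
  V_ANT: 4200.0
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
  f_ATP4_m: 0.005
  f_ATP4_e: 0.005
  Pi_m: 6.0
  Pi_e: 2.5
  Ca_m: 2.0e-4
  k_f: 0.009
  k_r: 1.0
  kinase_scale: 0.10
  D_ADP: 0.046
  D_ATP: 0.046
  as_flat_denominator: false
provenance:
  printed: [psi_m, f_P, k_f, k_r]
  calibrated: [V_ANT, kinase_scale, V_AS, K_ADP, K_ATP, K_Pi, K_Ca_ATP, K_V_ATP, Pi_m,
               Pi_e, Ca_m, D_ADP, D_ATP, f_ADP3_m, f_ADP3_e, f_ATP4_m,
               f_ATP4_e]
  notes: >
    T=310 K assumed (RT/F ~ 26.71 mV). k_r printed as "1 mM ms^-1" is read
    as 1 per mM per ms for the bimolecular mass-action term. Ionic
    fractions use standard free-species fractions of total ADP/ATP.
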