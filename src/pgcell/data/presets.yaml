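# Phenotype parameter presets: one document per published response type.
# Conductance densities in S/cm^2; absent channels are explicit zeros.
# Protocol amplitudes in pA, durations in ms (somatic current clamp).

passive:
  cm_uf_cm2: 1.2
  ra_ohm_cm: 173.0
  e_leak_mv: -70.0
  # uniform leak density calibrated to a 775 MOhm passive somatic input resistance
  g_leak_s_cm2: 2.649031e-4
  rin_target_mohm: 775.0
  rin_tol_mohm: 55.0

calcium:
  shell_depth_um: 0.1
  basal_mM: 2.4e-4
  decay_tau_ms: 5.0
  ca_out_mM: 2.0
  current_form: ghk

noise:
  sd_fA: 50.0
  bandwidth_khz: 4.0
  tau_ms: 5.0

model_defaults:
  cat_scope: soma
  nic_g_s_cm2: 0.005
  nic_e_mv: 3.2

presets:
  fig2A:
    response_type: non-accommodating
    description: Non-accommodating simple spike train
    gmax: {Na: 0.02, K: 0.01, K(A): 0.01, K(Ca): 0.0, H: 0.002, Ca(L): 0.0, Ca(T): 0.0, CAN: 0.0}
    e_leak_mv: -55.0
    noise_enabled: false
    protocol: {depol_pA: 3.5, depol_ms: 600.0, hyper_pA: -1.2, hyper_ms: 600.0}
  fig2B:
    response_type: accommodating
    description: Accommodating simple spike train
    gmax: {Na: 0.01, K: 0.001, K(A): 0.005, K(Ca): 0.0, H: 0.001, Ca(L): 0.0, Ca(T): 4.00e-4, CAN: 0.0}
    noise_enabled: false
    protocol: {depol_pA: 22.0, depol_ms: 600.0, hyper_pA: -22.0, hyper_ms: 600.0}
  fig2C:
    response_type: single-spike
    description: Single spike
    gmax: {Na: 0.01, K: 0.002, K(A): 0.02, K(Ca): 0.0, H: 0.0, Ca(L): 0.0, Ca(T): 2.00e-4, CAN: 0.0}
    noise_enabled: false
    protocol: {depol_pA: 25.0, depol_ms: 600.0, hyper_pA: -25.0, hyper_ms: 600.0}
  fig2D:
    response_type: irregular
    description: Irregular spiking (rare)
    gmax: {Na: 0.02, K: 0.01, K(A): 0.01, K(Ca): 0.0, H: 0.005, Ca(L): 0.0, Ca(T): 1.00e-4, CAN: 0.0}
    noise_enabled: true
    protocol: {depol_pA: 7.5, depol_ms: 600.0, hyper_pA: -20.0, hyper_ms: 600.0}
  fig3A:
    response_type: LTS-single-AP
    description: LTS with single AP
    gmax: {Na: 0.01, K: 0.1, K(A): 0.1, K(Ca): 0.0, H: 3.58e-5, Ca(L): 0.0, Ca(T): 0.005, CAN: 0.0}
    noise_enabled: false
    protocol: {depol_pA: 10.0, depol_ms: 600.0, hyper_pA: -10.0, hyper_ms: 600.0}
  fig3B:
    response_type: LTS-burst
    description: LTS with AP burst
    gmax: {Na: 0.011, K: 0.075, K(A): 0.025, K(Ca): 0.0, H: 3.58e-5, Ca(L): 0.0, Ca(T): 0.002, CAN: 0.0}
    noise_enabled: false
    protocol: {depol_pA: 10.0, depol_ms: 600.0, hyper_pA: -10.0, hyper_ms: 600.0}
  fig3C:
    response_type: plateau
    description: AP burst with extended plateau potential
    gmax: {Na: 0.004, K: 0.007, K(A): 0.001, K(Ca): 0.001, H: 0.0005, Ca(L): 0.001, Ca(T): 1.00e-4, CAN: 0.00128}
    noise_enabled: false
    protocol: {depol_pA: 30.0, depol_ms: 200.0, hyper_pA: -20.0, hyper_ms: 600.0}
  fig3D:
    response_type: plateau
    description: AP burst with extended plateau potential (no T current)
    gmax: {Na: 0.004, K: 0.007, K(A): 0.001, K(Ca): 0.001, H: 0.0005, Ca(L): 0.001, Ca(T): 0.0, CAN: 0.00128}
    noise_enabled: false
    protocol: {depol_pA: 30.0, depol_ms: 200.0, hyper_pA: -20.0, hyper_ms: 600.0}
  fig3E:
    response_type: plateau
    description: AP burst with extended plateau potential (reduced delayed rectifier)
    gmax: {Na: 0.004, K: 0.006, K(A): 0.001, K(Ca): 0.001, H: 0.0005, Ca(L): 0.001, Ca(T): 1.00e-4, CAN: 0.00128}
    noise_enabled: false
    protocol: {depol_pA: 30.0, depol_ms: 200.0, hyper_pA: -20.0, hyper_ms: 600.0}
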