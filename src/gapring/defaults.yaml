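# Default run configuration: the benchmark single-cell constants
# (g_fast, g_slow, tau_w bounds 5/50, k_tw, theta_tw) plus this package's
# package shape constants, a weak-coupling ring network, no noise.
cell:
  g_fast: 2.0
  g_slow: 2.0
  tau_m: 0.3
  tau_w_min: 5.0
  tau_w_max: 50.0
  k_tw: 0.2
  theta_tw: 0.16
  fast_shape: 0.3
  v_mid: 0.0
  v_scale: 0.28
  theta_slow: 0.16
  k_slow: 0.1
  w_floor: -0.425
network:
  N: 24
  topology: ring
  n_cc: 2
  g_el: 0.02
  chain_renormalize: false
noise:
  sigma: 0.0
  update_dt: 0.2
  seed: 0
stimulus:
  amplitude: 1.0
  duration: 0.2
  n_repeats: 3
  push_pull: true
solver:
  name: rk4
  h: 0.1
  rtol: 1.0e-06
classifier:
  tol_phase: 0.02
  v_threshold: null
  min_gap: 0.5
  transient_periods: 10.0
seed: 0
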