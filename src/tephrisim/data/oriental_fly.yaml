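# Oriental fruit fly (Bactrocera dorsalis) biodemographic parameter set.
name: oriental_fly
stages:
  egg_larva:
    delta: 136.0
    theta_L: 8.87
    theta_U: 36.5
    b: 3.25
    a: 0.00305
    erlang_k: 25
  pupa:
    delta: 177.0
    theta_L: 8.87
    theta_U: 36.5
    b: 3.25
    a: 0.00305
    erlang_k: 25
  adult:
    delta: 1050.0
    theta_L: 8.87
    theta_U: 36.5
    b: 3.25
    a: 0.00305
    erlang_k: 71
  quiescent_adult:
    delta: 1532.0
    theta_L: 8.87
    theta_U: 36.5
    b: 3.25
    a: 0.00305
    erlang_k: 71
reproduction:
  gamma: 2.3
  phi_base: 1.065
  x0: 16.0
  exp_offset: 1.5         # decay exponent is (x - 17.5) while the gate is x >= 16
  sr: 0.5
  H: 500.0
  alpha_coeff: 0.005
  T_opt: 25.0
  phi_T:
    form: polynomial      # cubic in T, ascending powers; clamped and max-normalized
    coeffs: [-14.603, 1.6652, -0.0567, 0.0006]
  phi_RH:
    form: window
    lo: 40.0
    hi: 95.0
mortality:
  egg_larva:
    form: polynomial
    coeffs: [0.2486, -0.0308056, 0.0024931, -0.0001116, 0.0000018]
  pupa_adult:
    form: alias
    of: egg_larva
rate_audit:
  - a: 0.00305
    stages: [egg_larva, pupa]    # published fit spans egg through pupa
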