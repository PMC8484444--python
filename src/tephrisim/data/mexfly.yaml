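# Mexican fruit fly (Anastrepha ludens) biodemographic parameter set.
name: mexfly
stages:
  egg_larva:
    delta: 258.0
    theta_L: 10.3
    theta_U: 34.0
    b: 4.0
    a: 0.0018
    erlang_k: 25
  pupa:
    delta: 264.0
    theta_L: 10.3
    theta_U: 34.0
    b: 4.0
    a: 0.0018
    erlang_k: 40
  adult:
    delta: 1000.0
    theta_L: 10.3
    theta_U: 34.0
    b: 4.0
    a: 0.0018
    erlang_k: 68
  quiescent_adult:
    delta: 1000.0
    theta_L: 10.3
    theta_U: 34.0
    b: 4.0
    a: 0.0018
    erlang_k: 68
reproduction:
  gamma: 2.355
  phi_base: 1.0475
  x0: 11.0
  exp_offset: 0.0
  sr: 0.5
  H: 500.0
  alpha_coeff: 0.005
  T_opt: 25.0
  phi_T:
    form: window
    lo: 12.78
    hi: 32.5
  phi_RH:
    # desiccation resistance is 36% higher than medfly: the medfly humidity
    # scalar is scaled up by 1.36 and clamped at 1.
    form: scaled_polynomial
    factor: 1.36
    coeffs: [0.15, 0.057917778, -0.001487393, 0.000016229, -0.000000063]
mortality:
  egg_larva:
    form: piecewise_exponential   # c1*exp(r1*T) below T_break, c2*exp(r2*T) at/above
    c1: 0.518
    r1: -0.690312
    c2: 0.00033
    r2: 0.1932889
    T_break: 10.3
  pupa_adult:
    form: alias
    of: egg_larva
rate_audit:
  - a: 0.0018
    stages: [egg_larva, pupa]    # published fit spans egg through pupa
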