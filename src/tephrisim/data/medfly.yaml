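# Mediterranean fruit fly (Ceratitis capitata) biodemographic parameter set.
# Coefficients are kept with the digits as published; do not round.
name: medfly
stages:
  egg_larva:
    delta: 129.0          # dd above theta_L
    theta_L: 10.345       # degC, lower developmental threshold
    theta_U: 33.5         # degC, upper inflection
    b: 2.75
    a: 0.031              # printed rate coefficient (egg-only fit; see audit notes)
    erlang_k: 25
  pupa:
    delta: 165.0
    theta_L: 9.5
    theta_U: 33.7
    b: 4.8
    a: 0.0059
    erlang_k: 40
  adult:
    delta: 772.0
    theta_L: 9.5
    theta_U: 33.7
    b: 4.8
    a: 0.0059
    erlang_k: 50
  quiescent_adult:
    delta: 1050.0
    theta_L: 9.5
    theta_U: 33.7
    b: 4.8
    a: 0.0059
    erlang_k: 50
reproduction:
  gamma: 6.25
  phi_base: 1.088
  x0: 3.0                 # pre-oviposition age offset, days at 25 degC
  exp_offset: 0.0         # extra offset in the decay exponent (days)
  sr: 0.5
  H: 500.0
  alpha_coeff: 0.005      # per dd of adult physiological time
  T_opt: 25.0
  phi_T:
    form: window
    lo: 15.0
    hi: 32.0
  phi_RH:
    # quartic in RH, ascending powers (constant first)
    form: polynomial
    coeffs: [0.15, 0.057917778, -0.001487393, 0.000016229, -0.000000063]
mortality:
  egg_larva:
    form: polynomial      # in T, ascending powers
    coeffs: [1.16, -0.217793, 0.015014, -0.000444, 0.000005]
  pupa_adult:
    form: polynomial
    coeffs: [0.1846, -0.018705, 0.000487]
# printed-rate vs 1/delta consistency audit: medfly egg-larval fit is egg-only
# and excluded; the adult-row coefficient covers pupal+adult shape only.
rate_audit: []
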