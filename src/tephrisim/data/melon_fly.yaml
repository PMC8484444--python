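# Melon fly (Bactrocera cucurbitae) biodemographic parameter set.
name: melon_fly
stages:
  egg_larva:
    delta: 104.0
    theta_L: 7.95
    theta_U: 33.5
    b: 4.0
    a: 0.00975
    erlang_k: 25
  pupa:
    delta: 164.0
    theta_L: 7.95
    theta_U: 33.5
    b: 4.0
    a: 0.00975
    erlang_k: 40
  adult:
    delta: 1197.0
    theta_L: 7.95
    theta_U: 33.5
    b: 4.0
    a: 0.00975
    erlang_k: 70
  quiescent_adult:
    delta: 1197.0
    theta_L: 7.95
    theta_U: 33.5
    b: 4.0
    a: 0.00975
    erlang_k: 70
reproduction:
  gamma: 2.55
  phi_base: 1.065
  x0: 4.0
  exp_offset: 0.0
  sr: 0.5
  H: 500.0
  alpha_coeff: 0.005
  T_opt: 25.0
  phi_T:
    form: rational        # a(T - theta_L)/(1 + b^(T - theta_U)); max-normalized
    a: 0.0034
    b: 1.85
    theta_L: 13.3
    theta_U: 34.2
  phi_RH:
    form: window
    lo: 35.0
    hi: 100.0
mortality:
  egg_larva:
    form: polynomial
    coeffs: [0.0909, -0.02999476, 0.00349784, -0.00015536, 0.00000232]
  pupa_adult:
    form: alias
    of: egg_larva
rate_audit:
  - a: 0.00975
    stages: [egg_larva]
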