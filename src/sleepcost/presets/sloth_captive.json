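{
  "q": 144,
  "kappa": 2.0,
  "eta": 1.0,
  "gamma": 0.8,
  "rho": 0.9,
  "nu_W": 8.0,
  "nu_S": 8.0,
  "lam": 0.2,
  "chi": 10.0,
  "mu_W": 5.614,
  "mu_S": -1.0,
  "xi": 1.0,
  "sigma": 0.0384
}
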