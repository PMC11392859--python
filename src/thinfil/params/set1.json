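{
  "kCa_plus": 350,
  "kCa_minus": 1000,
  "kSP_plus": 180,
  "kSP_minus": 292,
  "kIP_plus": 700,
  "kIP_minus": 225,
  "kMD_plus": 590,
  "kMD_minus": 225,
  "kref_BC": 675,
  "K_BC": 2.3,
  "f_XY": 225,
  "delta": 0.48,
  "lam": 0.008,
  "eta": 9,
  "mu": 9,
  "gamma": 70,
  "coupling_scale": 0.336928,
  "n_units": 26
}
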