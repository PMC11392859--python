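{
  "kCa_plus": 310,
  "kCa_minus": 1800,
  "kSP_plus": 225,
  "kSP_minus": 350,
  "kIP_plus": 1900,
  "kIP_minus": 225,
  "kMD_plus": 1650,
  "kMD_minus": 225,
  "kref_BC": 875,
  "K_BC": 2.0,
  "f_XY": 25,
  "delta": 0.4,
  "lam": 0.0001,
  "eta": 18,
  "mu": 18,
  "gamma": 50,
  "coupling_scale": 0.261362,
  "n_units": 26
}
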