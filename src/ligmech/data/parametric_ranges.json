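{
  "description": "Parameter ranges for the FRPHE parametric analysis.",
  "Ef_MPa": [10, 250],
  "Em_MPa": [1, 50],
  "nu_m": 0.4,
  "k0_1e-15_m4_per_Ns": [0.15, 15],
  "M": [1, 10]
}
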