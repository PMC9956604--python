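{
  "phenotype_shift": {
    "Braak": -0.9649999999999999,
    "MMSE": 4.479999999999999
  },
  "seed": 7
}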