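{
  "seed": 42,
  "sim": {"n_lines": 80, "snps_per_arm": 150},
  "n_perm": 200
}
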