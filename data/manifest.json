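{
  "seed": 0,
  "basal_length_um": 3290.0,
  "n_branches": 52,
  "n_synapses": 328
}
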