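{
  "hindiii": {
    "name": "hindiii",
    "description": "Lambda phage DNA / HindIII digest (564-23130 bp working set; the 125 bp fragment is routinely invisible and excluded)",
    "band_sizes_bp": [23130, 9416, 6557, 4361, 2322, 2027, 564],
    "threshold_candidates_bp": [23130, 9416, 6557, 4361, 2322, 2027]
  }
}
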