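{
  "name": "RII_like_synthetic_ref",
  "regions": {
    "nflank": [0, 10],
    "helix1": [10, 22],
    "loop": [22, 27],
    "helix2": [27, 40],
    "cflank": [40, 77]
  },
  "dimer_positions": [13, 14, 18, 21, 29, 34, 35],
  "docking_positions": [11, 15, 28, 31, 32],
  "consensus_ids": {
    "DPY30": "consensus_DPY30",
    "R1D2": "consensus_R1D2",
    "R2D2": "consensus_R2D2"
  }
}
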