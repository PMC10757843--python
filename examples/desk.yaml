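# Desk-scale synthetic volume: 64 slices of 128x128 with sparse nucleoli.
seed: 3
structure: nucleoli
synth:
  z: 64
  h: 128
  w: 128
  n_cells: 2
  nucleus_radius_range: [28, 40]
  nucleolus_radius_range: [4, 6]
  nucleolus_fg_target: 0.002
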