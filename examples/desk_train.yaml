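# CPS + CutMix training on the desk-scale synthetic volume from desk.yaml.
seed: 3
structure: nucleoli
trainer: cps_cutmix
n_labeled_slices: 3
output_dir: runs/desk
paths:
  volume: data/image.tif
  masks: data/nucleoli.tif
model:
  architecture: resunet
  depth: 2
  base_channels: 6
train:
  epochs: 40
  steps_per_epoch: 8
  batch_size: 8
  lr: 0.003
tiling:
  context_size: 64
  out_size: 32
  stride: 32
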