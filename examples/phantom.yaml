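# Reference desk-scale run configuration for the synthetic phantom cohort.
data:
  train_dir: data
  n_test: 2
  preprocess:
    target_slice_size: [64, 64]
    intensity_window: null        # phantoms are already in arbitrary units
    normalization: zscore
backbone:
  name: tiny
  seed: 7
  channels: 32
  stride: 8
model:
  head_channels: 32
  decoder_channels: [32, 16, 16, 8, 8]
  dropout_rate: 0.1
  num_classes: 2
losses:
  weights:
    w_cd: 1.0
    w_focal: 1.0
    w_tversky: 1.0
    w_logiou: 1.0
    w_entropy: 0.028
  biases:
    b_self: 0.15
    b_pos: 0.45
    b_neg: 0.80
train:
  batch_size: 8
  initial_lr: 1.0e-4
  weight_decay: 1.0e-5
  max_epochs: 20
  plateau_patience_epochs: 10
  lr_reduction_factor: 0.1
  seed: 7
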