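# Example thorseg configuration. Every section maps 1:1 onto a library
# dataclass; omitted keys take the documented defaults.

phantom:            # PhantomConfig — synthetic cohort geometry
  image_size: 128
  n_slices: 6
  spacing: [5.0, 3.0, 3.0]   # (dz, dy, dx) mm
  carina_slice: 2
  esophagus_air_fraction: [0.0, 0.8]
  noise_sd_hu: 15.0

network:            # NetworkConfig — used by train-stage1 / train-stage2
  n_classes: 6
  dense_stages: 3
  dense_layers_per_block: 2
  growth_rate: 8
  stem_width: 12
  widths: [8, 16, 32]        # residual-attention / baseline U-Net stages
  spatial_kernel: 7

train:              # TrainConfig
  epochs: 3
  batch_size: 4
  lr: 0.001
  dice_weight: 0.5

crop:               # CropSpec — stage-2 localization contract
  crop_size: 64
  shift_left_mm: 5.0
  shift_up_mm: 5.0
  jitter_range_mm: [0.0, 4.0]
  fallback_step_mm: 1.0
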