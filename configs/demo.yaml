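# Desk-scale synthetic demonstration: 36 slides (18 malignant / 18 benign)
# on an 8x8 patch grid, split 20 train / 6 validation / 10 test.
seed: 0
outdir: cytomil_run
synth:
  n_slides_malignant: 18
  n_slides_benign: 18
  grid_rows: 8
  grid_cols: 8
  patch_px: 64
  pos_patch_fraction: 0.2
  motif_contrast: 0.6
  noise_sd: 8.0
  seed: 0
split:
  train: 0.5555555555555556
  validation: 0.16666666666666666
  test: 0.2777777777777778
tiling:
  patch_px: 64
  model_px: 32
  keep_partial_edges: false
  background_filter: none
  background_threshold: 240.0
augment:
  jitter_brightness: 0.1
  jitter_contrast: 0.1
  jitter_saturation: 0.1
  seed: 0
mil:
  k_top: 10
  n_neg_random: 10
  epochs_stage1: 2
  epochs_stage2: 8
  learning_rate: 0.02
  momentum: 0.9
  batch_size: 32
  seed: 0
  init: random
  backbone: small_cnn
  input_px: 32
  iterate_rounds: 1
aggregation:
  patch_threshold: 0.5
  slide_threshold: 10
  score_mode: fraction
evaluation:
  n_boot: 2000
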