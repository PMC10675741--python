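# Example pipeline configuration: a small synthetic cohort.
# Activity entries are [name, mean duration s, sd s].
seed: 1

simulate:
  n_subjects: 8
  sampling_rate_hz: 40.0
  activities:
    - [walk, 120.0, 10.0]
    - [get_up_and_go, 50.0, 15.0]
  noise_sd: 0.3
  accel_clip: 40.0
  gyro_clip: 260.0

preprocess:
  window_s: 10.0
  overlap_s: 1.25
  train_fraction: 0.2    # train on 20%, evaluate on 80%
  normalize: zscore

augment:
  sd_scale: 0.05
  n_levels: 20
  max_drift: 0.5
  n_knots: 5
  noise_center: zero

model:
  embed_dim: 64
  kernel_size: 1         # search space: 1, 2, 4, 6, 8

train:
  batch_size: 4          # search space: 1, 4, 8, 16, 32
  learning_rate: 1.0e-3  # search space: 1e-2 ... 1e-5
  epochs: 10             # search space: 5 ... 50
  margin: 1.0
  loss_mix: 0.5

detect:
  weight_threshold: 0.1
  accel_threshold: 5.0
  jump_level: 15.0
  jump_window_ms: 300.0
  refractory_ms: 250.0
  projection: column

evaluate:
  modes: [before, after, centered]
  windows_ms: [125.0, 250.0, 500.0]
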