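# Desk-scale experiment configuration (see enteronet.presets and
# docs/methods.md): same architecture family as the full-size network,
# narrowed and shrunk so a complete 10-fold cross-validation runs in
# minutes on one CPU.
synthgen:
  n_cases_per_class: 10
  images_per_case: 5
  image_height: 200
  image_width: 200
  class_texture_params:
    control: {blob_density: 150.0, blob_eccentricity: 0.10, ridge_amplitude: 40.0,
              blob_radius: 3.5, ridge_period: 30.0, noise_sd: 2.0}
    CD:      {blob_density: 300.0, blob_eccentricity: 0.50, ridge_amplitude: 12.0,
              blob_radius: 6.0, ridge_period: 30.0, noise_sd: 2.0}
    EE:      {blob_density: 600.0, blob_eccentricity: 0.85, ridge_amplitude: 2.0,
              blob_radius: 9.0, ridge_period: 30.0, noise_sd: 2.0}

network:
  conv_feature_maps: [4, 8, 8, 16]
  conv_kernels: [5, 5, 5, 3]
  pool_windows: [2, 4, 5, 5]
  fc_width: 32
  dropout_p: 0.25
  input_size: 200

training:
  epochs: 20
  batch_size: 8
  learning_rate: 0.003

augmentation:
  n_train_patches: 1
  patch_size: 200
  gamma_range: [1.0, 1.0]
  include_reflections: false
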