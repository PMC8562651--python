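# 3D ResNet-18 on whole-lesion crops (strategy I), early stopping patience 10.
cohort: {preset: default, n_patients: 114, seed: 0}
split: {rare_threshold: 20, n_restarts: 50}
extract: {strategy: I, fixed_canvas_px: 145, target_hw: null}
augment: {enabled: true}
train:
  arch: resnet18_3d
  width_mult: 1.0
  lr0: 3.0e-3
  lr_drop_factor: 0.85
  lr_drop_every_epochs: 5
  weight_decay: 2.0e-4
  max_epochs: 100
  batch_size: 4
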