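# ResNeXt-50 (cardinality 32) on 2.5D strategy-C patches.
cohort: {preset: default, n_patients: 114, seed: 0}
split: {rare_threshold: 20, n_restarts: 50}
extract: {strategy: C, target_hw: 173}
augment: {enabled: true}
train:
  arch: resnext50_2d_c32
  width_mult: 1.0
  lr0: 1.0e-3
  lr_drop_factor: 0.8
  lr_drop_every_epochs: 7
  weight_decay: 2.0e-4
  max_epochs: 100
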