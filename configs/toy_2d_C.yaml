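# Desk-scale smoke run: 6-patient phantom cohort, width-reduced 2D ResNet-50,
# masked-texture patches (strategy C), 2 epochs.
cohort: {preset: separable, n_patients: 6, seed: 0}
extract: {strategy: C, target_hw: 32}
train: {arch: resnet50_2d, width_mult: 0.125, max_epochs: 2}
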