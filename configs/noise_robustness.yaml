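# Timing-noise robustness protocol: clean baseline plus the three Gaussian
# jitter settings, 75-25 split, desk scale.
schema_version: 1
generator: pheno
n_groups: 50
neurons_per_group: 15
duration: 2500.0
train_frac: 0.75
arch_id: slstm8
width_scale: 0.25
train:
  epochs: 15
noise:
  - [7.0, 4.0]
  - [15.0, 12.0]
  - [30.0, 25.0]
seed: 0
out_dir: results/noise_robustness
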