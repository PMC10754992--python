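# Scaled-down run of the three-detector metric comparison at the 60%-40%
# train-validation split.  Full scale is 1,000 groups x 15 neurons (30,000
# samples) and 100 epochs at unit width; this config runs the same protocol
# at desk scale.
schema_version: 1
generator: pheno
n_groups: 100
neurons_per_group: 10
duration: 2500.0
train_frac: 0.60
arch_id: slstm8
compare_archs: [slstm8, slstm7, snn7]
width_scale: 0.5
train:
  epochs: 25
  learning_rate: 0.05
  batch_size: 128
seed: 0
out_dir: results/table1_6040
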