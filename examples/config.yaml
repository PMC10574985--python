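# Example run configuration: a small five-level pipeline run.
scenario: five_level
seed: 7
out_dir: runs/demo
n_per_class: 40
epoch_len_s: 15
activation: t2f
target_total: 260
snr_grid_db: [-10, 0, 10, inf]
replicates: 3
gan:
  epochs: 3
  learning_rate: 0.0005
  optimizer: adam
train:
  optimizer: rmsprop
  max_epochs: 20
  patience: 20
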