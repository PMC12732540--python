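# Full-scale per-colorant experiment: `smafnet experiment --config examples/experiment.yaml`
# (three 200-epoch trainings; expect ~10 minutes on one CPU core)
design:
  n_pure: 45
  n_per_colorant: 100
  colorants: [sunset_yellow, tartrazine, ponceau_4r]
  seed: 42
split_ratio: 0.75
model:
  input_length: 267
train:
  epochs: 200
  batch_size: 16
  seed: 42
datasets:
  - [sunset_yellow, sunset_yellow]
  - [tartrazine, tartrazine]
  - [ponceau_4r, ponceau_4r]
out_dir: runs/experiment
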