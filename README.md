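# smafnet

Detection of trace artificial-colorant adulteration in black tea from
handheld near-infrared (NIR) spectra, using SMAFNet — a multi-scale,
attention-fused 1-D convolutional classifier — together with the SPXY
calibration/validation partitioner, the standard chemometric evaluation
metrics, and a synthetic spectra generator so the whole pipeline runs with
no external data.

**Who it is for:** chemometricians and food-safety practitioners screening
powdered black tea for azo colorants (Sunset Yellow, Tartrazine, Ponceau 4R)
at 0.1–0.5 g·kg⁻¹ — concentrations near the quantitative detection limit of
NIR, where the colorant signal is buried under natural pigment variation.

## The model

SMAFNet maps a raw absorbance vector **x** ∈ ℝᴸ (900–1700 nm grid) to
P(adulterated) through:

1. **SPM** — valid 1-D convolution (kernel 16, 64 channels,
   output length L − 15) + max-pool: a learned preprocessing filter bank.
2. **MSFEM** — n parallel branches with kernels of different sizes
   (default [1, 5, 9]), each a depth-d stack (default d = 2) of
   *feature-extraction blocks*: same-padded Conv1d → ReLU →
   squeeze-and-excitation channel attention → max-pool.
3. **CSAFM** — cross-scale attention fusion. For reference scale r and each
   partner j ≠ r:

       Z_j = Concat(X_r, X_j)
       a_j = σ(Conv₂(ReLU(Conv₁(Z_j))))      a_j ∈ (0,1)
       X̂_j = a_j ⊙ X_j
       F_r = X_r + Σ_{j≠r} X̂_j

4. **Head** — flatten/concatenate all F_r → dense(128) + ReLU → single
   sigmoid unit.

Training: binary cross-entropy, Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-8),
200 epochs, batch 16, fully seeded. Evaluation: ACC/PRE/REC (percent) and F1
from the TP/TN/FP/FN confusion matrix with "adulterated" as positive class.
Splits use SPXY (greedy max–min selection on max-normalized joint spectral +
label distances). Everything is NumPy with hand-derived, finite-difference-
verified gradients; see `docs/methods.md` for the full model account.

## Worked example

```python
import numpy as np
from smafnet import (SyntheticDesign, generate_dataset, spxy_split,
                     SMAFNetConfig, TrainConfig, train_model, evaluate)

data = generate_dataset(SyntheticDesign(seed=42))   # 345 spectra, 267 points
subset = data.filter_colorant("sunset_yellow")      # 45 pure + 100 adulterated
split = spxy_split(subset, ratio=0.75)
cal, val = subset.subset(split.calibration_idx), subset.subset(split.validation_idx)
print(len(split.calibration_idx), len(split.validation_idx))

model, hist = train_model(SMAFNetConfig(), TrainConfig(seed=42), cal, val)
cm, report = evaluate(model, val)
print((cm.tp, cm.tn, cm.fp, cm.fn), round(report.acc, 2), round(report.f1, 4))
```

prints (training takes a few minutes on one CPU core):

```
109 36
(21, 15, 0, 0) 100.0 1.0
```

109/36 is the SPXY partition of the 145-sample Sunset-Yellow dataset at the
customary 75 % calibration ratio. The confusion counts say all 21 adulterated
and all 15 pure validation samples were classified correctly, giving 100 %
accuracy and F1 = 1.0 on this synthetic design — the trace colorant band
(≤ 0.02 absorbance units) is recovered despite scatter and noise.

The same pipeline is scriptable from the shell:

```sh
smafnet simulate --out tea.csv --seed 42
smafnet split --in tea.csv --ratio 0.75 --out split.csv
smafnet train --data tea.csv --indices split.csv --seed 42 --out model.npz
smafnet eval --checkpoint model.npz --data tea.csv --indices split.csv --out metrics.json
smafnet experiment --config examples/experiment.yaml   # full per-colorant protocol
```

Short narrative scripts for each capability live in `examples/`.

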