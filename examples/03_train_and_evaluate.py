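"""Train the default SMAFNet on the Sunset-Yellow dataset and evaluate it.

Full-scale run (109 calibration spectra, 200 epochs): takes a few minutes on
one CPU core. The printed confusion matrix and metrics are computed on the
36 SPXY-held-out validation samples.
"""

from smafnet import (SMAFNetConfig, SyntheticDesign, TrainConfig, evaluate,
                     generate_dataset, spxy_split, train_model)

data = generate_dataset(SyntheticDesign(seed=42)).filter_colorant("sunset_yellow")
split = spxy_split(data, ratio=0.75)
cal = data.subset(split.calibration_idx)
val = data.subset(split.validation_idx)

model, hist = train_model(SMAFNetConfig(), TrainConfig(seed=42), cal, val)
cm, report = evaluate(model, val)
r = report.rounded()

print(f"final training loss: {hist.train_loss[-1]:.4f}")
print(f"confusion: TP={cm.tp} TN={cm.tn} FP={cm.fp} FN={cm.fn}")
print(f"ACC {r.acc}%  PRE {r.pre}%  REC {r.rec}%  F1 {r.f1}")
# REC (recall) is the food-safety-critical number: the fraction of
# adulterated samples caught; FN=0 means zero missed detections
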