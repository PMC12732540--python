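"""Partition a dataset with SPXY and compare with a random split.

SPXY picks calibration samples by greedy max-min selection on the joint
spectral + label distance, so the calibration set spans the data cloud and
the two most-distant samples always train the model.
"""

import numpy as np

from smafnet import SyntheticDesign, combined_distance, generate_dataset, spxy_split

data = generate_dataset(SyntheticDesign(seed=0)).filter_colorant("sunset_yellow")
split = spxy_split(data, ratio=0.75)

print(f"N={data.n_samples} -> {len(split.calibration_idx)} calibration / "
      f"{len(split.validation_idx)} validation")

cal_labels = data.labels[list(split.calibration_idx)]
val_labels = data.labels[list(split.validation_idx)]
print(f"calibration: {(cal_labels == 0).sum()} pure + {(cal_labels == 1).sum()} adulterated")
print(f"validation:  {(val_labels == 0).sum()} pure + {(val_labels == 1).sum()} adulterated")

d = combined_distance(data.absorbance, data.labels)
i, j = split.calibration_idx[0], split.calibration_idx[1]
print(f"seed pair ({i}, {j}) has the largest joint distance: {d[i, j]:.3f} "
      f"(max over all pairs: {d.max():.3f})")
# both terms of the joint distance are max-normalized, so 2.0 would mean the
# pair is extreme in spectral space AND has opposite labels
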