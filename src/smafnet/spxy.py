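"""SPXY calibration/validation partitioning.

SPXY (sample-set partitioning based on joint X-Y distances) is a
Kennard-Stone-style greedy max-min selector that measures sample distance in
both the spectral space X and the response space Y:

    d(i, j) = dx(i, j) / max dx  +  dy(i, j) / max dy

with dx the Euclidean distance between spectra and dy the absolute response
difference (here Y is the binary adulteration status, so dy is 0 or 1).
Selection seeds with the mutually most-distant pair and repeatedly adds the
sample whose minimum distance to the already-selected set is largest, until
the calibration set holds ceil(ratio * N) samples; the remainder is the
validation set.  Ties break toward the smallest index, making the split fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .spectra import SpectraSet

__all__ = ["SplitResult", "combined_distance", "spxy_split"]


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/validation index sets in selection order."""

    calibration_idx: tuple[int, ...]
    validation_idx: tuple[int, ...]
    ratio: float

    def __post_init__(self) -> None:
        cal, val = set(self.calibration_idx), set(self.validation_idx)
        if cal & val:
            raise ValueError("calibration and validation sets overlap")
        n = len(self.calibration_idx) + len(self.validation_idx)
        if cal | val != set(range(n)):
            raise ValueError("split does not cover all sample indices")


def combined_distance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Max-normalized joint spectral + response distance matrix.

    Each term is scaled by its largest pairwise value so X and Y contribute
    on equal footing; when all responses are equal the Y term is dropped and
    the distance reduces to pure Kennard-Stone behavior.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an N x L matrix with N >= 2")
    if y.shape != (X.shape[0],):
        raise ValueError("y must have one response per row of X")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")

    dx = squareform(pdist(X, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    d = np.zeros_like(dx)
    if dx.max() > 0:
        d += dx / dx.max()
    if dy.max() > 0:
        d += dy / dy.max()
    return d


def spxy_split(spectra: SpectraSet, ratio: float = 0.75) -> SplitResult:
    """Greedy max-min SPXY split of a SpectraSet.

    The calibration set receives ceil(ratio * N) samples (a 145-sample dataset
    at the customary 0.75 ratio yields 109 calibration / 36 validation).  Once
    selected for calibration a sample never moves, so the validation set is
    genuinely unseen.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    n = spectra.n_samples
    if n < 2:
        raise ValueError("need at least two samples to split")

    d = combined_distance(spectra.absorbance, spectra.labels)
    n_cal = ceil(ratio * n)

    # seed: the mutually most-distant pair, smallest indices on ties
    flat = np.argmax(d)  # argmax scans row-major -> smallest (i, j) wins ties
    i, j = divmod(int(flat), n)
    selected = [min(i, j), max(i, j)]
    if n_cal == 1:
        selected = selected[:1]

    # min distance from every sample to the selected set, updated incrementally
    min_d = np.minimum(d[selected[0]], d[selected[-1]])
    min_d[selected] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(min_d))  # argmax takes the first max -> smallest index
        selected.append(nxt)
        min_d = np.minimum(min_d, d[nxt])
        min_d[nxt] = -np.inf

    cal = tuple(selected)
    val = tuple(k for k in range(n) if k not in set(cal))
    return SplitResult(calibration_idx=cal, validation_idx=val, ratio=ratio)
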