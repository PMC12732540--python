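"""Independent explicit-loop oracles shared by the unit and acceptance suites.

These deliberately re-derive each operation with plain Python loops so they
stay independent of the vectorized implementations they check.
"""

from math import ceil

import numpy as np

from smafnet import SpectraSet


def conv_oracle(x, W, b):
    """Triple-loop valid cross-correlation, (B, Cin, T) x (Cout, Cin, k)."""
    batch, c_in, t = x.shape
    c_out, _, k = W.shape
    y = np.zeros((batch, c_out, t - k + 1))
    for n in range(batch):
        for j in range(c_out):
            for pos in range(t - k + 1):
                acc = 0.0
                for c in range(c_in):
                    for i in range(k):
                        acc += x[n, c, pos + i] * W[j, c, i]
                y[n, j, pos] = acc + (b[j] if b is not None else 0.0)
    return y


def se_oracle(x, fc1_W, fc1_b, fc2_W, fc2_b):
    """Explicit three-stage squeeze/excitation/reweight computation."""
    batch, c, t = x.shape
    out = np.zeros_like(x)
    for n in range(batch):
        z = np.array([x[n, ch].mean() for ch in range(c)])
        h = np.maximum(fc1_W @ z + fc1_b, 0.0)
        s = 1.0 / (1.0 + np.exp(-(fc2_W @ h + fc2_b)))
        for ch in range(c):
            out[n, ch] = x[n, ch] * s[ch]
    return out


def as_spectra_set(X, y):
    """Wrap a plain matrix + binary labels into a valid SpectraSet."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    grid = 900.0 + 3.0 * np.arange(X.shape[1])
    return SpectraSet(
        wavelengths=grid,
        absorbance=X,
        labels=y,
        colorant=np.where(y == 1, "tartrazine", "none"),
        concentration=np.where(y == 1, 0.3, 0.0),
        sample_id=np.array([f"s{i}" for i in range(len(y))], dtype=object),
    )


def oracle_combined_distance(X, y):
    """Explicit-loop joint distance: dx/max dx + dy/max dy."""
    n = len(y)
    dx = np.zeros((n, n))
    dy = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dx[i, j] = np.sqrt(np.sum((X[i] - X[j]) ** 2))
            dy[i, j] = abs(float(y[i]) - float(y[j]))
    d = np.zeros((n, n))
    if dx.max() > 0:
        d += dx / dx.max()
    if dy.max() > 0:
        d += dy / dy.max()
    return d


def oracle_spxy(X, y, ratio):
    """Brute-force greedy max-min selection with smallest-index tie-breaks."""
    d = oracle_combined_distance(np.asarray(X, float), y)
    n = len(y)
    n_cal = ceil(ratio * n)
    best, pair = -1.0, (0, 1)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > best:
                best, pair = d[i, j], (i, j)
    selected = list(pair)[:n_cal]
    while len(selected) < n_cal:
        best_val, best_idx = -1.0, None
        for cand in range(n):
            if cand in selected:
                continue
            mind = min(d[cand, s] for s in selected)
            if mind > best_val:
                best_val, best_idx = mind, cand
        selected.append(best_idx)
    return tuple(selected)
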