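"""Domain containers for NIR spectra and their on-disk CSV form.

A spectrum is an absorbance curve sampled on a strictly increasing wavelength
grid (nm); handheld NIR instruments in the 900-1700 nm window produce one such
curve per scan.  ``SpectraSet`` is the exchange object every other module
consumes: an N x L absorbance matrix plus binary adulteration labels, colorant
tags and colorant concentrations (g/kg).

The CSV dialect is fixed on purpose: comma-separated, UTF-8, dot decimals,
mandatory header ``id,label,colorant,concentration,<wavelength>,...`` where the
remaining column names are the numeric wavelength grid.  One file fully
describes one dataset; there is no sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLORANTS",
    "Spectrum",
    "SpectraSet",
    "SpectraFormatError",
    "SpectraValidationError",
    "default_grid",
    "read_spectra_csv",
    "write_spectra_csv",
    "average_scans",
]

#: Recognized colorant tags; "none" marks a pure (unadulterated) sample.
COLORANTS = ("none", "sunset_yellow", "tartrazine", "ponceau_4r")

_META_COLUMNS = ("id", "label", "colorant", "concentration")


class SpectraFormatError(ValueError):
    """Raised when a spectra CSV does not follow the fixed dialect."""


class SpectraValidationError(ValueError):
    """Raised when spectral data violate a domain invariant."""


def default_grid(start: float = 900.0, stop: float = 1698.0, step: float = 3.0) -> np.ndarray:
    """Default wavelength grid: 900-1698 nm in 3 nm steps (267 points).

    The instrument range is 900-1700 nm at 3 nm resolution; the exact point
    count is a convention, so the grid stays an explicit argument everywhere.
    """
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def _check_grid(wavelengths: np.ndarray) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise SpectraValidationError("wavelength grid must be a non-empty 1-D vector")
    if not np.all(np.isfinite(w)):
        raise SpectraValidationError("wavelength grid contains non-finite values")
    if not np.all(np.diff(w) > 0):
        raise SpectraValidationError("wavelengths must be strictly increasing")
    return w


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance curve on a wavelength grid (nm)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        w = _check_grid(self.wavelengths)
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != w.shape:
            raise SpectraValidationError(
                f"absorbance length {a.shape} does not match grid {w.shape}"
            )
        if not np.all(np.isfinite(a)):
            raise SpectraValidationError("absorbance contains non-finite values")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "absorbance", a)

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass
class SpectraSet:
    """A labelled collection of spectra sharing one wavelength grid.

    Invariants: ``label == 0`` iff ``colorant == "none"`` iff
    ``concentration == 0``; sample ids are unique; all arrays agree on N.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    labels: np.ndarray
    colorant: np.ndarray
    concentration: np.ndarray
    sample_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavelengths = _check_grid(self.wavelengths)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise SpectraValidationError("absorbance must be an N x L matrix")
        n, length = self.absorbance.shape
        if n < 1:
            raise SpectraValidationError("a SpectraSet needs at least one sample")
        if length != self.wavelengths.size:
            raise SpectraValidationError(
                f"absorbance has {length} columns but grid has {self.wavelengths.size} points"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraValidationError("absorbance contains non-finite values")

        self.labels = np.asarray(self.labels)
        if self.labels.shape != (n,) or not np.isin(self.labels, (0, 1)).all():
            raise SpectraValidationError("labels must be N binary values in {0, 1}")
        self.labels = self.labels.astype(np.int64)

        self.colorant = np.asarray(self.colorant, dtype=object)
        if self.colorant.shape != (n,):
            raise SpectraValidationError("colorant must have one tag per sample")
        bad = set(self.colorant) - set(COLORANTS)
        if bad:
            raise SpectraValidationError(f"unknown colorant tags: {sorted(bad)}")

        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.concentration.shape != (n,) or np.any(self.concentration < 0):
            raise SpectraValidationError("concentration must be N non-negative values")

        if self.sample_id is None:
            self.sample_id = np.array([f"s{i:04d}" for i in range(n)], dtype=object)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        if self.sample_id.shape != (n,):
            raise SpectraValidationError("sample_id must have one entry per sample")
        if len(set(self.sample_id)) != n:
            raise SpectraValidationError("sample ids must be unique")

        pure = self.labels == 0
        if not np.array_equal(pure, self.colorant == "none"):
            raise SpectraValidationError('label 0 must coincide with colorant "none"')
        if not np.array_equal(pure, self.concentration == 0):
            raise SpectraValidationError("label 0 must coincide with concentration 0")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, idx: Sequence[int]) -> "SpectraSet":
        """New SpectraSet restricted to the given sample indices (order kept)."""
        idx = np.asarray(idx, dtype=int)
        return SpectraSet(
            wavelengths=self.wavelengths,
            absorbance=self.absorbance[idx],
            labels=self.labels[idx],
            colorant=self.colorant[idx],
            concentration=self.concentration[idx],
            sample_id=self.sample_id[idx],
        )

    def filter_colorant(self, tag: str) -> "SpectraSet":
        """Pure samples plus samples adulterated with one given colorant."""
        if tag not in COLORANTS or tag == "none":
            raise ValueError(f"expected an adulterant tag, got {tag!r}")
        keep = np.flatnonzero((self.colorant == "none") | (self.colorant == tag))
        return self.subset(keep)


def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read a spectra CSV into a validated :class:`SpectraSet`.

    The column order of the wavelength columns defines the grid.  Parsing is
    locale-independent (dot decimal separator).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str, "colorant": str})
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise SpectraFormatError(f"missing required column {col!r} in {path}")
    if len(df.columns) != len(set(df.columns)):
        raise SpectraFormatError(f"duplicate columns in {path}")
    wl_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if not wl_cols:
        raise SpectraFormatError(f"no wavelength columns in {path}")
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavelength column name: {exc}") from None
    labels = df["label"].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise SpectraValidationError("labels must be 0 or 1")
    return SpectraSet(
        wavelengths=wavelengths,
        absorbance=df[wl_cols].to_numpy(dtype=float),
        labels=labels,
        colorant=df["colorant"].to_numpy(dtype=object),
        concentration=df["concentration"].to_numpy(dtype=float),
        sample_id=df["id"].to_numpy(dtype=object),
    )


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    """Write a SpectraSet to CSV; round-trips absorbance to >=12 significant digits."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "id": spectra.sample_id,
            "label": spectra.labels,
            "colorant": spectra.colorant,
            "concentration": spectra.concentration,
        }
    )
    spec_df = pd.DataFrame(
        spectra.absorbance, columns=[format(w, "g") for w in spectra.wavelengths]
    )
    df = pd.concat([df, spec_df], axis=1)
    # repr-level float precision so read(write(s)) is bit-faithful
    df.to_csv(path, index=False, float_format="%.17g")


def average_scans(replicates: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate scans of one sample.

    Instruments scan each sample several times (six by default in this
    workflow) and the mean spectrum is carried forward, which shrinks
    independent point noise by 1/sqrt(n_scans).
    """
    if len(replicates) < 1:
        raise SpectraValidationError("need at least one replicate scan")
    grid = replicates[0].wavelengths
    for rep in replicates[1:]:
        if rep.wavelengths.shape != grid.shape or not np.array_equal(rep.wavelengths, grid):
            raise SpectraValidationError("replicate scans must share one wavelength grid")
    mean = np.mean([rep.absorbance for rep in replicates], axis=0)
    return Spectrum(wavelengths=grid, absorbance=mean)
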