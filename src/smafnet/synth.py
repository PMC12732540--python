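"""Synthetic black-tea NIR spectra with controlled trace adulteration.

The generator emulates the statistical structure of powdered black tea
measured on a handheld 900-1700 nm spectrometer:

* a smooth pure-tea absorbance curve — a gentle linear baseline plus Gaussian
  absorption bands at the positions reported for fermented tea (a weak C-H/O-H
  second-overtone band near 1195 nm, the strong O-H first-overtone band near
  1465 nm, and catechin-related bands at 1656/1680 nm);
* trace azo-colorant adulteration at 0.10-0.50 g/kg, which slightly and
  multiplicatively depresses the tea absorbance and adds a small
  colorant-specific band, both linear in concentration;
* per-sample multiplicative gain and additive offset scatter (residual
  particle-size/packing effects after sieving);
* i.i.d. per-point instrument noise on each of six replicate scans, which are
  averaged exactly as an operator would average them.

Band shapes are Gaussians — the standard surrogate for NIR overtone bands
when only positions are known.  Defaults reproduce the study inventory:
45 pure samples plus 100 per colorant for three colorants (345 spectra).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .spectra import COLORANTS, SpectraSet, Spectrum, average_scans, default_grid

__all__ = ["SyntheticDesign", "tea_baseline", "apply_adulteration", "generate_dataset"]

#: colorant tag -> (band center nm, band width nm, band amplitude per g/kg)
_DEFAULT_COLORANT_BANDS: dict[str, tuple[float, float, float]] = {
    "sunset_yellow": (1520.0, 22.0, 0.040),
    "tartrazine": (1560.0, 22.0, 0.040),
    "ponceau_4r": (1600.0, 22.0, 0.040),
}


def _gauss(w: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((w - center) / width) ** 2)


@dataclass(frozen=True)
class SyntheticDesign:
    """Full description of one synthetic dataset.

    Amplitudes are unitless absorbance; widths and centers are nm;
    ``global_effect`` is the fractional absorbance decrease per g/kg of
    adulterant; ``colorant_band`` amplitudes are absorbance per g/kg.
    """

    n_pure: int = 45
    n_per_colorant: int = 100
    colorants: tuple[str, ...] = ("sunset_yellow", "tartrazine", "ponceau_4r")
    concentrations: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.501, 0.05), 2))
    wavelengths: np.ndarray = field(default_factory=default_grid)
    band_centers: tuple[float, ...] = (1195.0, 1465.0, 1656.0, 1680.0)
    band_widths: tuple[float, ...] = (30.0, 45.0, 14.0, 14.0)
    band_amplitudes: tuple[float, ...] = (0.05, 0.30, 0.08, 0.10)
    baseline_offset: float = 0.40
    baseline_slope: float = 2.0e-4
    global_effect: float = 0.02
    colorant_band: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COLORANT_BANDS)
    )
    scatter_mult_sd: float = 0.010
    scatter_add_sd: float = 0.002
    noise_sd: float = 0.004
    n_scans: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pure < 0 or self.n_per_colorant < 0:
            raise ValueError("sample counts must be non-negative")
        unknown = set(self.colorants) - (set(COLORANTS) - {"none"})
        if unknown:
            raise ValueError(f"unknown colorants: {sorted(unknown)}")
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size and (np.any(conc <= 0) or np.any(np.diff(conc) <= 0)):
            raise ValueError("concentrations must be strictly positive and sorted")
        if len(self.band_centers) != len(self.band_widths) or len(self.band_centers) != len(
            self.band_amplitudes
        ):
            raise ValueError("band centers/widths/amplitudes must have equal lengths")
        if any(w <= 0 for w in self.band_widths):
            raise ValueError("band widths must be positive")
        if min(self.scatter_mult_sd, self.scatter_add_sd, self.noise_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.n_scans < 1:
            raise ValueError("need at least one scan per sample")
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, dtype=float))

    def with_(self, **changes) -> "SyntheticDesign":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def tea_baseline(wavelengths: np.ndarray, design: SyntheticDesign) -> np.ndarray:
    """Deterministic pure-tea absorbance curve on the given grid.

    Linear baseline plus the design's Gaussian bands.  With default
    amplitudes the strong O-H band dominates, so the curve peaks inside
    1430-1500 nm while the 1170-1220 nm band stays weak.
    """
    w = np.asarray(wavelengths, dtype=float)
    curve = design.baseline_offset + design.baseline_slope * (w - w[0])
    for center, width, amp in zip(design.band_centers, design.band_widths, design.band_amplitudes):
        curve = curve + amp * _gauss(w, center, width)
    return curve


def apply_adulteration(
    baseline: np.ndarray, colorant: str, conc: float, design: SyntheticDesign
) -> np.ndarray:
    """Adulterated clean spectrum for one colorant at one concentration.

    The colorant depresses tea absorbance multiplicatively
    (``baseline * (1 - global_effect * conc)``) and contributes its own small
    Gaussian band, linear in concentration.  Both effects are monotone in
    ``conc``; away from the colorant band the output never exceeds the pure
    baseline.
    """
    if conc <= 0:
        raise ValueError("concentration must be positive for adulterated samples")
    if colorant not in design.colorant_band:
        raise ValueError(f"no colorant band defined for {colorant!r}")
    center, width, amp = design.colorant_band[colorant]
    base = np.asarray(baseline, dtype=float)
    return base * (1.0 - design.global_effect * conc) + amp * conc * _gauss(
        design.wavelengths, center, width
    )


def _measure(
    clean: np.ndarray, design: SyntheticDesign, rng: np.random.Generator
) -> np.ndarray:
    """One measured sample: scatter draw, n_scans noisy scans, scan average."""
    gain = 1.0 + rng.normal(0.0, design.scatter_mult_sd)
    offset = rng.normal(0.0, design.scatter_add_sd)
    sample = gain * clean + offset
    scans = [
        Spectrum(design.wavelengths, sample + rng.normal(0.0, design.noise_sd, clean.size))
        for _ in range(design.n_scans)
    ]
    return average_scans(scans).absorbance


def generate_dataset(design: SyntheticDesign) -> SpectraSet:
    """Simulate a full labelled dataset, reproducible from ``design.seed``.

    Pure samples come first, then ``n_per_colorant`` samples per colorant in
    the design's colorant order.  Concentrations cycle through the design grid
    (9 levels by default) so 100 samples per colorant cover every level nearly
    uniformly.
    """
    if design.n_per_colorant > 0 and not design.colorants:
        raise ValueError("n_per_colorant > 0 requires at least one colorant")
    if design.n_pure + design.n_per_colorant * len(design.colorants) < 1:
        raise ValueError("design produces an empty dataset")

    rng = np.random.default_rng(design.seed)
    base = tea_baseline(design.wavelengths, design)
    conc_grid = list(design.concentrations)

    rows, labels, tags, concs, ids = [], [], [], [], []
    for i in range(design.n_pure):
        rows.append(_measure(base, design, rng))
        labels.append(0)
        tags.append("none")
        concs.append(0.0)
        ids.append(f"pure_{i:03d}")
    for tag in design.colorants:
        for i in range(design.n_per_colorant):
            conc = conc_grid[i % len(conc_grid)]
            clean = apply_adulteration(base, tag, conc, design)
            rows.append(_measure(clean, design, rng))
            labels.append(1)
            tags.append(tag)
            concs.append(conc)
            ids.append(f"{tag}_{i:03d}")

    return SpectraSet(
        wavelengths=design.wavelengths,
        absorbance=np.array(rows),
        labels=np.array(labels),
        colorant=np.array(tags, dtype=object),
        concentration=np.array(concs),
        sample_id=np.array(ids, dtype=object),
    )
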