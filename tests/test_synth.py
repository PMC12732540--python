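"""Synthetic generator: band structure, adulteration effects, reproducibility."""

import numpy as np
import pytest

from smafnet import SyntheticDesign, apply_adulteration, generate_dataset, tea_baseline
from smafnet.spectra import default_grid


@pytest.fixture(scope="module")
def design():
    return SyntheticDesign(seed=5)


class TestTeaBaseline:
    def test_null_design_gives_zero_curve(self):
        d = SyntheticDesign(
            band_amplitudes=(0.0, 0.0, 0.0, 0.0), baseline_offset=0.0, baseline_slope=0.0
        )
        curve = tea_baseline(d.wavelengths, d)
        assert np.allclose(curve, 0.0)

    def test_argmax_in_strong_band_window(self, design):
        # the O-H first-overtone band dominates: peak falls in 1430-1500 nm
        curve = tea_baseline(design.wavelengths, design)
        peak = design.wavelengths[np.argmax(curve)]
        assert 1430.0 <= peak <= 1500.0

    def test_strong_band_exceeds_weak_band(self, design):
        w = design.wavelengths
        curve = tea_baseline(w, design)
        strong = curve[(w >= 1430) & (w <= 1500)].max()
        weak = curve[(w >= 1170) & (w <= 1220)].max()
        assert strong > weak

    def test_single_band_peak_identity(self):
        d = SyntheticDesign(
            band_centers=(1200.0,),
            band_widths=(25.0,),
            band_amplitudes=(0.7,),
            baseline_offset=0.1,
            baseline_slope=0.0,
        )
        curve = tea_baseline(d.wavelengths, d)
        at_center = curve[np.argmin(np.abs(d.wavelengths - 1200.0))]
        assert np.isclose(at_center, 0.1 + 0.7)


class TestApplyAdulteration:
    def test_zero_effect_is_identity(self):
        d = SyntheticDesign(
            global_effect=0.0,
            colorant_band={"sunset_yellow": (1520.0, 22.0, 0.0)},
        )
        base = tea_baseline(d.wavelengths, d)
        out = apply_adulteration(base, "sunset_yellow", 0.3, d)
        assert np.array_equal(out, base)

    def test_deviation_linear_in_concentration(self, design):
        base = tea_baseline(design.wavelengths, design)
        d1 = apply_adulteration(base, "tartrazine", 0.2, design) - base
        d2 = apply_adulteration(base, "tartrazine", 0.4, design) - base
        assert np.allclose(d2, 2.0 * d1)

    def test_mean_absorbance_decreases(self, design):
        # colorants slightly depress overall absorbance
        base = tea_baseline(design.wavelengths, design)
        out = apply_adulteration(base, "sunset_yellow", 0.5, design)
        assert out.mean() < base.mean()

    def test_no_increase_outside_colorant_band(self, design):
        base = tea_baseline(design.wavelengths, design)
        out = apply_adulteration(base, "ponceau_4r", 0.5, design)
        center, width, _ = design.colorant_band["ponceau_4r"]
        away = np.abs(design.wavelengths - center) > 5 * width
        assert np.all(out[away] <= base[away])

    def test_nonpositive_concentration_rejected(self, design):
        base = tea_baseline(design.wavelengths, design)
        with pytest.raises(ValueError):
            apply_adulteration(base, "tartrazine", 0.0, design)


class TestGenerateDataset:
    def test_reference_scale_inventory(self, default_dataset):
        # 45 pure + 3 x 100 adulterated = 345 spectra
        assert default_dataset.n_samples == 345
        assert int((default_dataset.labels == 0).sum()) == 45
        for tag in ("sunset_yellow", "tartrazine", "ponceau_4r"):
            assert int((default_dataset.colorant == tag).sum()) == 100

    def test_single_sample_design(self):
        d = SyntheticDesign(n_pure=0, n_per_colorant=1, colorants=("tartrazine",))
        out = generate_dataset(d)
        assert out.n_samples == 1 and out.labels[0] == 1

    def test_empty_colorants_with_samples_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(SyntheticDesign(n_per_colorant=5, colorants=()))

    def test_degenerate_design_collapses_to_baseline(self):
        d = SyntheticDesign(
            n_pure=2,
            n_per_colorant=2,
            colorants=("sunset_yellow",),
            global_effect=0.0,
            colorant_band={"sunset_yellow": (1520.0, 22.0, 0.0)},
            scatter_mult_sd=0.0,
            scatter_add_sd=0.0,
            noise_sd=0.0,
        )
        out = generate_dataset(d)
        base = tea_baseline(d.wavelengths, d)
        assert np.allclose(out.absorbance, base[None, :])

    def test_same_seed_bitwise_identical(self, design):
        a = generate_dataset(design)
        b = generate_dataset(design)
        assert np.array_equal(a.absorbance, b.absorbance)
        assert np.array_equal(a.labels, b.labels)

    def test_different_seed_same_label_structure(self, design):
        a = generate_dataset(design)
        b = generate_dataset(design.with_(seed=design.seed + 1))
        assert not np.array_equal(a.absorbance, b.absorbance)
        assert np.array_equal(a.labels, b.labels)
        assert list(a.colorant) == list(b.colorant)
        assert np.array_equal(a.concentration, b.concentration)

    def test_concentration_grid_cycles_nearly_uniformly(self, default_dataset):
        sy = default_dataset.concentration[default_dataset.colorant == "sunset_yellow"]
        counts = {c: int((sy == c).sum()) for c in np.unique(sy)}
        assert len(counts) == 9  # all nine levels present
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_adulterated_mean_below_pure_mean_outside_bands(self, default_dataset):
        d = SyntheticDesign(seed=7)
        mu_pure = default_dataset.absorbance[default_dataset.labels == 0].mean(axis=0)
        mu_adul = default_dataset.absorbance[default_dataset.labels == 1].mean(axis=0)
        away = np.ones(d.wavelengths.size, dtype=bool)
        for center, width, _ in d.colorant_band.values():
            away &= np.abs(d.wavelengths - center) > 3 * width
        assert np.all(mu_adul[away] <= mu_pure[away])

    def test_class_separation_monotone_in_effect(self):
        # distance between class means grows with the global effect size
        seps = []
        for effect in (0.0, 0.02, 0.05):
            d = SyntheticDesign(
                n_pure=20, n_per_colorant=20, colorants=("tartrazine",),
                global_effect=effect, seed=9,
            )
            out = generate_dataset(d)
            mu0 = out.absorbance[out.labels == 0].mean(axis=0)
            mu1 = out.absorbance[out.labels == 1].mean(axis=0)
            seps.append(float(np.linalg.norm(mu1 - mu0)))
        assert seps[0] < seps[1] < seps[2]
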