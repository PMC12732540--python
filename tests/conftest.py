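import numpy as np
import pytest

from smafnet import SMAFNetConfig, SyntheticDesign, generate_dataset
from smafnet.model import CSAFMConfig, MSFEMConfig, SPMConfig


@pytest.fixture(scope="session")
def small_design() -> SyntheticDesign:
    """A fast, strongly separable design on a short grid for training tests."""
    grid = 900.0 + 3.0 * np.arange(64)
    return SyntheticDesign(
        n_pure=24,
        n_per_colorant=24,
        colorants=("sunset_yellow",),
        wavelengths=grid,
        band_centers=(960.0, 1020.0),
        band_widths=(20.0, 25.0),
        band_amplitudes=(0.10, 0.25),
        colorant_band={"sunset_yellow": (990.0, 15.0, 0.20)},
        global_effect=0.05,
        noise_sd=0.002,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return generate_dataset(small_design)


@pytest.fixture(scope="session")
def tiny_model_config() -> SMAFNetConfig:
    """A small architecture matching the 64-point grid of small_design."""
    return SMAFNetConfig(
        input_length=64,
        spm=SPMConfig(kernel_size=8, out_channels=16),
        msfem=MSFEMConfig(kernel_sizes=(3, 7), depth=1, channels=16, se_reduction=4),
        csafm=CSAFMConfig(),
        head_hidden=32,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Paper-scale default synthetic dataset (345 spectra)."""
    return generate_dataset(SyntheticDesign(seed=7))
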