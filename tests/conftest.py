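import numpy as np
import pytest

from dermometry.images import CalibratedImage
from dermometry.synthetic import (
    SynthHistologyParams,
    SynthTemParams,
    generate_he_section,
    generate_tem_bundle,
)


@pytest.fixture(scope="session")
def he_section():
    """Default synthetic H&E field at 25% amorphous target, seed 1."""
    params = SynthHistologyParams(target_amorphous_fraction=0.25, seed=1)
    image, truth = generate_he_section(params)
    return params, image, truth


@pytest.fixture(scope="session")
def tem_bundle():
    """Default synthetic wavy TEM bundle (5 fibrils, 8 nm/px), seed 2."""
    params = SynthTemParams(seed=2)
    image, truth = generate_tem_bundle(params)
    return params, image, truth


@pytest.fixture(scope="session")
def fibril_field():
    """Fibril-scale field (3 fibrils at 2 nm/px) for transect measurements."""
    params = SynthTemParams(
        image_size=(224, 256),
        pixel_size_nm=2.0,
        fibril_diameter_nm=85.0,
        interfibrillar_gap_nm=18.0,
        n_fibrils=3,
        d_period_nm=62.0,
        d_band_contrast=0.3,
        centerline_amplitude_nm=20.0,
        centerline_wavelength_nm=1500.0,
        seed=3,
    )
    image, truth = generate_tem_bundle(params)
    return params, image, truth


@pytest.fixture(scope="session")
def dband_fibril():
    """Single-fibril field with strong 62 nm axial banding."""
    params = SynthTemParams(
        image_size=(64, 320),
        pixel_size_nm=2.0,
        fibril_diameter_nm=80.0,
        interfibrillar_gap_nm=20.0,
        n_fibrils=1,
        d_period_nm=62.0,
        d_band_contrast=0.4,
        centerline_amplitude_nm=10.0,
        centerline_wavelength_nm=1500.0,
        seed=4,
    )
    image, truth = generate_tem_bundle(params)
    return params, image, truth


def straight_ribbon(
    width_px: int = 20,
    pixel_size_nm: float = 10.0,
    shape: tuple[int, int] = (64, 128),
    dark: float = 0.4,
    bright: float = 0.85,
) -> CalibratedImage:
    """Noiseless horizontal dark ribbon centred in the image."""
    img = np.full(shape, bright)
    r0 = (shape[0] - width_px) // 2
    img[r0 : r0 + width_px, :] = dark
    return CalibratedImage(img, pixel_size_nm, "TEM")
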