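import numpy as np
import pytest

from magrule.optics import ScoreCategory
from magrule.stain import StainMatrix
from magrule.synth import CategoryPreset, SpecimenConfig


@pytest.fixture
def hdab() -> StainMatrix:
    return StainMatrix.hdab()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def single_cell_config(
    width_um: float,
    amplitude: float = 0.8,
    noise_sd: float = 0.0,
    psf_sigma_um: float = 0.10,
    completeness: float = 1.0,
    seed: int = 7,
    **kwargs,
) -> SpecimenConfig:
    """A deterministic one-cell specimen with exactly known width/amplitude."""
    preset = CategoryPreset(
        score=ScoreCategory.TWO_PLUS,
        width_mean_um=width_um,
        width_sd_um=0.0,
        amp_slope=0.0,
        amp_intercept=amplitude,
        amp_noise_sd=0.0,
    )
    defaults = dict(
        preset=preset,
        n_cells=1,
        cell_radius_um=(7.0, 7.0),
        psf_sigma_um=psf_sigma_um,
        rgb_noise_sd=noise_sd,
        background_hema_od=0.0,
        canvas_um=30.0,
        completeness=completeness,
        seed=seed,
    )
    defaults.update(kwargs)
    return SpecimenConfig(**defaults)


def box_gauss_fwhm(width_um: float, sigma_um: float, dx: float = 1e-4) -> float:
    """Independent 1-D oracle: FWHM of a box of width w convolved with a
    Gaussian of SD sigma, computed by numerical convolution on a fine grid."""
    span = width_um / 2 + 6 * sigma_um + 0.5
    n = int(2 * span / dx) | 1
    x = np.linspace(-span, span, n)
    dx = x[1] - x[0]
    box = (np.abs(x) <= width_um / 2).astype(float)
    if sigma_um > 0:
        kx = np.arange(-6 * sigma_um, 6 * sigma_um + dx / 2, dx)
        kernel = np.exp(-0.5 * (kx / sigma_um) ** 2)
        kernel /= kernel.sum()
        profile = np.convolve(box, kernel, mode="same")
    else:
        profile = box
    half = profile.max() / 2
    above = np.where(profile >= half)[0]
    lo, hi = above[0], above[-1]

    def cross(i0, i1):
        y0, y1 = profile[i0], profile[i1]
        return x[i0] + (half - y0) / (y1 - y0) * (x[i1] - x[i0])

    left = cross(lo - 1, lo) if lo > 0 else x[lo]
    right = cross(hi + 1, hi) if hi < n - 1 else x[hi]
    return right - left
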