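"""Beer-Lambert stain mixing and color deconvolution.

Chromogens absorb light multiplicatively, so per-channel optical density
``OD_c = -log10(I_c / I0)`` is additive across stains.  With unit OD vectors
for each stain, a pixel's OD is a linear combination of stain vectors and
can be unmixed by inverting the stain matrix (linear unmixing in OD space).
The same matrix runs forwards to render synthetic images (:func:`remix`) and
backwards on measured images (:func:`deconvolve`), which gives the simulator
and the measurement pipeline a shared, exactly invertible color model
(up to 8-bit quantization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "RUIFROK_HEMATOXYLIN_OD",
    "RUIFROK_DAB_OD",
    "StainVector",
    "StainMatrix",
    "RGBImage",
    "ODImage",
    "rgb_to_od",
    "deconvolve",
    "transmitted_rgb",
    "remix",
    "dab_intensity_pct",
    "separate_stains",
]

# Published H-DAB optical-density vectors (unit-normalized below).
RUIFROK_HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
RUIFROK_DAB_OD = (0.269, 0.568, 0.778)


@dataclass(frozen=True)
class StainVector:
    """A named, unit-normalized optical-density direction in RGB space."""

    name: str
    od_rgb: Tuple[float, float, float]

    def __post_init__(self) -> None:
        vec = np.asarray(self.od_rgb, dtype=float)
        if vec.shape != (3,):
            raise ValueError(f"stain vector must have 3 components, got {vec.shape}")
        if np.any(vec < 0):
            raise ValueError(f"stain OD components must be non-negative: {self.od_rgb}")
        norm = float(np.linalg.norm(vec))
        if norm <= 0:
            raise ValueError("stain vector must have at least one positive component")
        object.__setattr__(self, "od_rgb", tuple(float(v) for v in vec / norm))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.od_rgb, dtype=float)


@dataclass(frozen=True)
class StainMatrix:
    """Two or three stain vectors forming an invertible 3x3 OD mixing matrix.

    With two stains the third row is their (normalized) cross product — an
    orthogonal residual direction that absorbs out-of-plane color noise
    without contaminating the named stain channels.
    """

    stains: Tuple[StainVector, ...]

    def __post_init__(self) -> None:
        if len(self.stains) not in (2, 3):
            raise ValueError("StainMatrix requires 2 or 3 stain vectors")
        m = self.matrix
        if abs(np.linalg.det(m)) < 1e-9:
            raise ValueError("stain matrix is singular; stain vectors are collinear")

    @classmethod
    def hdab(cls) -> "StainMatrix":
        """Default hematoxylin + DAB matrix (published unmixing vectors)."""
        return cls(
            (
                StainVector("hematoxylin", RUIFROK_HEMATOXYLIN_OD),
                StainVector("dab", RUIFROK_DAB_OD),
            )
        )

    @property
    def stain_names(self) -> Tuple[str, ...]:
        return tuple(s.name for s in self.stains)

    @property
    def matrix(self) -> np.ndarray:
        """Full 3x3 matrix; row ``s`` is the OD vector of stain ``s``."""
        rows = [s.array for s in self.stains]
        if len(rows) == 2:
            residual = np.cross(rows[0], rows[1])
            norm = np.linalg.norm(residual)
            if norm < 1e-12:
                raise ValueError("stain vectors are collinear; no residual direction")
            rows.append(residual / norm)
        return np.vstack(rows)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def index_of(self, name: str) -> int:
        try:
            return self.stain_names.index(name)
        except ValueError:
            raise KeyError(f"no stain named {name!r} in {self.stain_names}") from None


@dataclass
class RGBImage:
    """8-bit RGB raster with a physical pixel scale (pixels per micrometer)."""

    pixels: np.ndarray
    pixel_scale: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be positive")
        self.pixels = px

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ODImage:
    """Per-stain concentration maps (base-10 OD units), one H x W plane per stain."""

    conc: np.ndarray  # H x W x n_stains
    stain_names: Tuple[str, ...]
    pixel_scale: float

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.stain_names.index(name)
        except ValueError:
            raise KeyError(f"no stain channel {name!r} in {self.stain_names}") from None
        return self.conc[..., idx]


def rgb_to_od(pixels: np.ndarray, i0: float = 255.0, eps: float = 1.0) -> np.ndarray:
    """Per-channel optical density ``-log10(max(I, eps) / I0)``.

    ``eps`` (default one grey level) floors the intensity so fully black
    pixels map to a large finite OD instead of infinity.
    """
    if not i0 > 0:
        raise ValueError("white level i0 must be positive")
    img = np.asarray(pixels, dtype=float)
    return -np.log10(np.maximum(img, eps) / i0)


def deconvolve(
    od: np.ndarray, stain_matrix: StainMatrix, clip_negative: bool = True
) -> np.ndarray:
    """Unmix a per-channel OD raster into per-stain concentrations.

    Solves ``od = conc @ M`` per pixel for the full 3-row matrix and returns
    the named-stain columns (the residual channel is dropped for 2-stain
    matrices).  Negative solutions — out-of-gamut colors — are clipped to 0.
    """
    od = np.asarray(od, dtype=float)
    if od.shape[-1] != 3:
        raise ValueError(f"OD raster must have 3 channels, got shape {od.shape}")
    conc = od @ stain_matrix.inverse
    conc = conc[..., : len(stain_matrix.stains)]
    if clip_negative:
        conc = np.maximum(conc, 0.0)
    return conc


def transmitted_rgb(
    conc: np.ndarray, stain_matrix: StainMatrix, i0: float = 255.0
) -> np.ndarray:
    """Forward Beer-Lambert model, un-quantized: ``I_c = I0 * 10^(-sum_s c_s M_sc)``."""
    conc = np.asarray(conc, dtype=float)
    n = len(stain_matrix.stains)
    if conc.shape[-1] == n:
        m = stain_matrix.matrix[:n]
    elif conc.shape[-1] == 3:
        m = stain_matrix.matrix
    else:
        raise ValueError(
            f"concentration raster must have {n} or 3 channels, got {conc.shape}"
        )
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    od = conc @ m
    return i0 * np.power(10.0, -od)


def remix(conc: np.ndarray, stain_matrix: StainMatrix, i0: float = 255.0) -> np.ndarray:
    """Render concentrations to a quantized 8-bit RGB array."""
    out = np.round(transmitted_rgb(conc, stain_matrix, i0))
    return np.clip(out, 0, 255).astype(np.uint8)


def dab_intensity_pct(od_values: np.ndarray) -> float:
    """Relative staining intensity of a region, percent.

    The mean OD of the region is rendered back to an 8-bit grey level
    ``G = round(255 * 10^(-mean OD))`` and reported on the inverted relative
    scale ``100 * (255 - G) / 255`` — 0% is white (unstained), 100% is black
    (fully saturated staining).
    """
    values = np.asarray(od_values, dtype=float)
    if values.size == 0:
        raise ValueError("intensity region must be non-empty")
    mean_od = float(np.mean(values))
    grey = float(np.round(255.0 * 10.0 ** (-mean_od)))
    grey = min(max(grey, 0.0), 255.0)
    return 100.0 * (255.0 - grey) / 255.0


def separate_stains(
    image: RGBImage, stain_matrix: Optional[StainMatrix] = None
) -> ODImage:
    """Convenience: RGB image -> per-stain OD concentration image."""
    if stain_matrix is None:
        stain_matrix = StainMatrix.hdab()
    od = rgb_to_od(image.pixels)
    conc = deconvolve(od, stain_matrix)
    return ODImage(conc, stain_matrix.stain_names, image.pixel_scale)
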