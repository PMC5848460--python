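"""Objective optics and width-based scoring windows.

A light-microscope objective resolves two points only if they are farther
apart than the diffraction limit ``d = lambda / (2 * NA)``.  A membranous
chromogen band narrower than ``d`` cannot be delineated through that
objective, which is what turns the set of standard diagnostic objectives
(5x, 10x, 20x, 40x/100x) into a coarse width-measurement instrument: the
lowest magnification at which the band is recognizable brackets its width.

This module provides the two formulas (:func:`numerical_aperture`,
:func:`abbe_resolution`), objective descriptions (:class:`ObjectiveSpec`),
and the mapping from a measured band width to a semi-quantitative score
0 / 1+ / 2+ / 3+ (:func:`classify_width` with :class:`ScoreThresholds`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Optional, Sequence

__all__ = [
    "DEFAULT_WAVELENGTH_NM",
    "ScoreCategory",
    "ScoreThresholds",
    "ObjectiveSpec",
    "DEFAULT_OBJECTIVES",
    "numerical_aperture",
    "abbe_resolution",
    "default_thresholds",
    "classify_width",
]

#: Mid-spectrum design wavelength (nm) used for the default resolution table.
DEFAULT_WAVELENGTH_NM = 600.0


class ScoreCategory(IntEnum):
    """Semi-quantitative membrane-staining score, totally ordered.

    ``ZERO`` means no measurable precipitate.  The integer values make the
    ordering explicit: ``ZERO < ONE_PLUS < TWO_PLUS < THREE_PLUS``.
    """

    ZERO = 0
    ONE_PLUS = 1
    TWO_PLUS = 2
    THREE_PLUS = 3

    @property
    def label(self) -> str:
        """Conventional string form: ``"0"``, ``"1+"``, ``"2+"``, ``"3+"``."""
        return _SCORE_LABELS[int(self)]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label

    @classmethod
    def from_label(cls, label) -> "ScoreCategory":
        """Parse ``"2+"``, ``2`` or a ScoreCategory into a ScoreCategory."""
        if isinstance(label, cls):
            return label
        if isinstance(label, int) and not isinstance(label, bool):
            return cls(label)
        text = str(label).strip()
        for value, name in _SCORE_LABELS.items():
            if text == name or text == str(value):
                return cls(value)
        raise ValueError(f"unknown score label: {label!r}")


_SCORE_LABELS = {0: "0", 1: "1+", 2: "2+", 3: "3+"}


def numerical_aperture(n: float, half_angle_deg: float) -> float:
    """Numerical aperture ``NA = n * sin(alpha)`` of an objective.

    Parameters
    ----------
    n:
        Refractive index of the immersion medium (>= 1; air is 1.0).
    half_angle_deg:
        Half-angle ``alpha`` of the maximum light cone, in degrees,
        in the interval (0, 90].

    Returns
    -------
    float
        The numerical aperture, in (0, n].
    """
    if not n >= 1.0:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    if not 0.0 < half_angle_deg <= 90.0:
        raise ValueError(
            f"half-angle must be in (0, 90] degrees, got {half_angle_deg}"
        )
    return n * math.sin(math.radians(half_angle_deg))


def abbe_resolution(wavelength_nm: float, na: float) -> float:
    """Diffraction-limited resolution ``d = lambda / (2 * NA)`` in micrometers.

    ``d`` is the minimum distance between two points on the focal plane that
    the objective can still separate.  The wavelength is given in nanometers
    and the result converted to micrometers, hence the factor 2000.
    """
    if not wavelength_nm > 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    if not na > 0:
        raise ValueError(f"numerical aperture must be positive, got {na}")
    return wavelength_nm / (2000.0 * na)


@dataclass(frozen=True)
class ObjectiveSpec:
    """A microscope objective with enough data to compute its resolution.

    Either the numerical aperture is given directly, or it is implied by the
    half-angle and medium index; if both are given they must agree.
    """

    name: str
    nominal_magnification: float
    numerical_aperture: float
    medium_refractive_index: float = 1.0
    half_angle_deg: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.nominal_magnification > 0:
            raise ValueError("nominal_magnification must be positive")
        if not self.medium_refractive_index >= 1.0:
            raise ValueError("medium_refractive_index must be >= 1")
        na = self.numerical_aperture
        if not 0.0 < na <= self.medium_refractive_index + 1e-9:
            raise ValueError(
                f"numerical aperture {na} outside (0, n={self.medium_refractive_index}]"
            )
        if self.half_angle_deg is not None:
            implied = numerical_aperture(
                self.medium_refractive_index, self.half_angle_deg
            )
            if abs(implied - na) > 1e-9:
                raise ValueError(
                    f"half-angle implies NA={implied!r}, but NA={na!r} was given"
                )

    def resolution_um(self, wavelength_nm: float = DEFAULT_WAVELENGTH_NM) -> float:
        """Abbe resolution of this objective, micrometers."""
        return abbe_resolution(wavelength_nm, self.numerical_aperture)


#: Standard diagnostic objectives and their typical numerical apertures.
DEFAULT_OBJECTIVES: Sequence[ObjectiveSpec] = (
    ObjectiveSpec("5x", 5, 0.14),
    ObjectiveSpec("10x", 10, 0.30),
    ObjectiveSpec("20x", 20, 0.50),
    ObjectiveSpec("100x", 100, 0.75),
)


@dataclass(frozen=True)
class ScoreThresholds:
    """Lower width bounds (micrometers) of the 1+, 2+ and 3+ windows.

    The windows partition [0, inf): ``[0, w1) -> 0``, ``[w1, w2) -> 1+``,
    ``[w2, w3) -> 2+``, ``[w3, inf) -> 3+``.  Lower bounds are inclusive so
    a width exactly on a cutoff falls in the higher category.
    """

    w_min_1plus: float = 0.4
    w_min_2plus: float = 1.0
    w_min_3plus: float = 2.0

    def __post_init__(self) -> None:
        a, b, c = self.w_min_1plus, self.w_min_2plus, self.w_min_3plus
        if not (0.0 < a < b < c):
            raise ValueError(
                f"thresholds must be strictly increasing and positive, got {(a, b, c)}"
            )

    def as_tuple(self) -> tuple:
        return (self.w_min_1plus, self.w_min_2plus, self.w_min_3plus)


def default_thresholds() -> ScoreThresholds:
    """The rounded resolution-window cutoffs 0.4 / 1.0 / 2.0 micrometers.

    These are the resolutions of the 40x, 10x and 5x objectives as commonly
    quoted; note that for the 5x objective (NA 0.14) the Abbe formula itself
    yields 2.14 um at 600 nm — the 2.0 um figure is the conventional rounded
    value.  Override via :class:`ScoreThresholds` if the exact formula values
    are preferred.
    """
    return ScoreThresholds()


def classify_width(
    width_um: Optional[float], thresholds: Optional[ScoreThresholds] = None
) -> ScoreCategory:
    """Map a measured band width to its score category.

    ``None`` (or NaN) is the sentinel for "no measurable precipitate" and
    maps to score 0.  Negative widths are a domain error.
    """
    if thresholds is None:
        thresholds = default_thresholds()
    if width_um is None or (isinstance(width_um, float) and math.isnan(width_um)):
        return ScoreCategory.ZERO
    if width_um < 0:
        raise ValueError(f"width must be non-negative, got {width_um}")
    if width_um >= thresholds.w_min_3plus:
        return ScoreCategory.THREE_PLUS
    if width_um >= thresholds.w_min_2plus:
        return ScoreCategory.TWO_PLUS
    if width_um >= thresholds.w_min_1plus:
        return ScoreCategory.ONE_PLUS
    return ScoreCategory.ZERO
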