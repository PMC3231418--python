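"""RGB -> CIE L*a*b* colour transform used by the classifier.

The working colour representation is CIE L*a*b*: lightness L* in [0, 100]
and the two opponent axes a* (green-red) and b* (blue-yellow).  The
transform chain is the classical one: normalised RGB is mapped to CIE XYZ
tristimulus values by a fixed 3x3 matrix, and XYZ is mapped to Lab
relative to a reference white point through the piecewise cube-root
compression ``f(t)``.

Field photographs carry strong illumination gradients; Lab is used
because its lightness axis absorbs most of that variation, leaving the
chromatic axes to separate green, dried and intermediate vegetation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvalidImageError

__all__ = [
    "RGB_TO_XYZ_MATRIX",
    "WhitePoint",
    "EQUAL_ENERGY_WHITE",
    "rgb_to_xyz",
    "xyz_to_lab",
    "rgb_to_lab",
    "quantize_channels",
]

#: CIE RGB -> XYZ matrix (unit-range primaries).
RGB_TO_XYZ_MATRIX = np.array(
    [
        [0.490, 0.310, 0.200],
        [0.177, 0.813, 0.011],
        [0.000, 0.010, 0.990],
    ]
)

#: Breakpoint of the piecewise compression f(t).
_F_BREAKPOINT = 0.008856
#: Slope of the linear L* branch: 116 * (7.787 t + 16/116) - 16 = 903.3 t.
_LOW_L_SLOPE = 903.3


@dataclass(frozen=True)
class WhitePoint:
    """Reference-white tristimulus values (Xn, Yn, Zn), all strictly positive."""

    xn: float
    yn: float
    zn: float

    def __post_init__(self):
        if not (self.xn > 0 and self.yn > 0 and self.zn > 0):
            raise ConfigurationError(
                f"white point must be strictly positive, got {(self.xn, self.yn, self.zn)}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.xn, self.yn, self.zn])


#: Image of RGB = (1, 1, 1) under the conversion matrix: the equal-energy
#: white for this primary set, used when no white point is supplied.
EQUAL_ENERGY_WHITE = WhitePoint(*RGB_TO_XYZ_MATRIX.sum(axis=1))


def _as_pixels(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim < 1 or arr.shape[-1] != 3:
        raise InvalidImageError(f"expected a (..., 3) array, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise InvalidImageError("image contains non-finite values")
    return arr


def rgb_to_xyz(image: np.ndarray, max_value: float | None = None) -> np.ndarray:
    """Convert an RGB raster to CIE XYZ tristimulus values.

    Parameters
    ----------
    image : (..., 3) array
        RGB values in ``[0, max_value]``.
    max_value : float, optional
        Channel range; inferred from the dtype for integer inputs
        (255 for uint8, 65535 for uint16), 1.0 for floating inputs.
    """
    if max_value is None:
        dt = np.asarray(image).dtype
        max_value = float(np.iinfo(dt).max) if np.issubdtype(dt, np.integer) else 1.0
    if max_value <= 0:
        raise ConfigurationError(f"max_value must be positive, got {max_value}")
    rgb = _as_pixels(image) / max_value
    return rgb @ RGB_TO_XYZ_MATRIX.T


def _f(t: np.ndarray) -> np.ndarray:
    """Piecewise compression: t^(1/3) above the breakpoint, linear below."""
    t = np.asarray(t, dtype=float)
    return np.where(t > _F_BREAKPOINT, np.cbrt(np.maximum(t, 0.0)), 7.787 * t + 16.0 / 116.0)


def xyz_to_lab(
    image: np.ndarray,
    white: WhitePoint = EQUAL_ENERGY_WHITE,
    low_branch: str = "linear",
) -> np.ndarray:
    """Convert XYZ tristimulus values to CIE L*a*b*.

    ``low_branch`` selects the L* formula below the breakpoint
    Y/Yn = 0.008856:

    - ``"linear"`` (default): L* = 903.3 * (Y/Yn), the branch that joins
      the upper 116*(Y/Yn)^(1/3) - 16 branch continuously and is implied
      by the same f(t) used for a* and b*;
    - ``"cube_root"``: L* = 903.3 * (Y/Yn)^(1/3), an alternative
      discontinuous form found in some formulations.
    """
    if low_branch not in ("linear", "cube_root"):
        raise ConfigurationError(f"unknown lab low-branch mode: {low_branch!r}")
    xyz = _as_pixels(image)
    ratios = xyz / white.as_array()
    xr, yr, zr = ratios[..., 0], ratios[..., 1], ratios[..., 2]

    low = _LOW_L_SLOPE * (np.cbrt(np.maximum(yr, 0.0)) if low_branch == "cube_root" else yr)
    lightness = np.where(yr > _F_BREAKPOINT, 116.0 * np.cbrt(np.maximum(yr, 0.0)) - 16.0, low)
    fy = _f(yr)
    a_star = 500.0 * (_f(xr) - fy)
    b_star = 200.0 * (fy - _f(zr))
    return np.stack([lightness, a_star, b_star], axis=-1)


def rgb_to_lab(
    image: np.ndarray,
    white: WhitePoint = EQUAL_ENERGY_WHITE,
    max_value: float | None = None,
    low_branch: str = "linear",
) -> np.ndarray:
    """Composite RGB -> XYZ -> Lab conversion."""
    return xyz_to_lab(rgb_to_xyz(image, max_value=max_value), white=white, low_branch=low_branch)


def quantize_channels(
    lab: np.ndarray,
    l_levels: int = 101,
    ab_levels: int = 221,
    ab_range: tuple[float, float] = (-110.0, 110.0),
) -> np.ndarray:
    """Quantize a Lab raster to integer histogram bins per channel.

    L* is mapped linearly from [0, 100] onto ``0 .. l_levels-1``; a* and
    b* from ``ab_range`` onto ``0 .. ab_levels-1``.  Values outside the
    nominal ranges are clipped.  The thresholding stage operates on
    histograms of these integer levels.
    """
    if l_levels < 2 or ab_levels < 2:
        raise ConfigurationError("need at least 2 quantization levels per channel")
    lab = _as_pixels(lab)
    lo, hi = ab_range
    if not hi > lo:
        raise ConfigurationError(f"invalid a*/b* range {ab_range}")
    out = np.empty(lab.shape, dtype=np.int64)
    out[..., 0] = np.clip(np.rint(lab[..., 0] / 100.0 * (l_levels - 1)), 0, l_levels - 1)
    scale = (ab_levels - 1) / (hi - lo)
    for c in (1, 2):
        out[..., c] = np.clip(np.rint((lab[..., c] - lo) * scale), 0, ab_levels - 1)
    return out
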