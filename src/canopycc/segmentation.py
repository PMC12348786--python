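"""HSV-threshold vegetation segmentation of canopy RGB images.

A pixel counts as vegetation when its hue lies inside an inclusive window
(wrapping through 0 deg when ``hue_min > hue_max``), its saturation strictly
exceeds ``sat_min`` and its value lies strictly below ``val_max``.  The
default window 50-180 deg with S > 0.1 and V < 0.95 separates green/yellow
foliage from soil (low hue), bright equipment (high value) and achromatic
background (low saturation).  Red-purple foliage needs a wrapped per-species
window (e.g. 300-40 deg) because its hue sits near 0/360 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv


@dataclass(frozen=True)
class HSVThresholds:
    """Segmentation rule parameters: hue window (deg), min saturation, max value."""

    hue_min: float = 50.0
    hue_max: float = 180.0
    sat_min: float = 0.1
    val_max: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.hue_min < 360.0 and 0.0 <= self.hue_max < 360.0):
            raise ValueError("hue bounds must lie in [0, 360)")
        if not 0.0 <= self.sat_min < 1.0:
            raise ValueError("sat_min must lie in [0, 1)")
        if not 0.0 < self.val_max <= 1.0:
            raise ValueError("val_max must lie in (0, 1]")

    @property
    def wraps(self) -> bool:
        return self.hue_min > self.hue_max


DEFAULT_THRESHOLDS = HSVThresholds()


@dataclass(frozen=True)
class VegetationMask:
    """Boolean per-pixel vegetation map with a cached vegetation count."""

    grid: np.ndarray
    n_vegetation: int

    def __post_init__(self) -> None:
        if self.grid.dtype != bool or self.grid.ndim != 2:
            raise ValueError("mask grid must be a 2-D boolean array")
        if int(self.grid.sum()) != self.n_vegetation:
            raise ValueError("n_vegetation inconsistent with grid")


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {image.shape}")
    if image.dtype != np.uint8:
        arr = np.asarray(image, dtype=float)
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("digital numbers must lie in [0, 255]")
    return image


def hsv_image(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel (hue deg in [0,360), saturation, value) of an 8-bit RGB image.

    Uses the standard hexagonal convention: V = max/255, S = (max-min)/max
    (0 for black), hue from the dominant sector.
    """
    image = _validate_image(image)
    hsv = rgb2hsv(np.asarray(image, dtype=np.uint8))
    return hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2]


def rgb_to_hsv(r: float, g: float, b: float) -> tuple[float, float, float]:
    """Convert one DN triplet in [0, 255] to (hue deg, saturation, value)."""
    for name, v in (("r", r), ("g", g), ("b", b)):
        if not 0 <= v <= 255:
            raise ValueError(f"DN {name}={v} outside [0, 255]")
    pixel = np.array([[[r, g, b]]], dtype=np.uint8)
    h, s, v = hsv_image(pixel)
    return float(h[0, 0]), float(s[0, 0]), float(v[0, 0])


def segment_vegetation(
    image: np.ndarray,
    thr: HSVThresholds = DEFAULT_THRESHOLDS,
    *,
    despeckle: bool = False,
) -> VegetationMask:
    """Apply the HSV rule pixel-wise and return the binary vegetation mask.

    Hue bounds are inclusive; saturation and value comparisons are strict.
    ``despeckle`` optionally removes vegetation pixels with no vegetation
    8-neighbour (off by default: the rule is pure thresholding).
    """
    h, s, v = hsv_image(image)
    if thr.wraps:
        in_hue = (h >= thr.hue_min) | (h <= thr.hue_max)
    else:
        in_hue = (h >= thr.hue_min) & (h <= thr.hue_max)
    grid = in_hue & (s > thr.sat_min) & (v < thr.val_max)
    if despeckle:
        neighbours = ndimage.convolve(
            grid.astype(np.uint8), np.ones((3, 3), dtype=np.uint8), mode="constant"
        ) - grid.astype(np.uint8)
        grid = grid & (neighbours > 0)
    return VegetationMask(grid=grid, n_vegetation=int(grid.sum()))


def vegetation_fraction(mask: VegetationMask) -> float:
    """Fraction of pixels classified as vegetation."""
    total = mask.grid.size
    if total == 0:
        raise ValueError("zero-pixel mask")
    return mask.n_vegetation / total
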