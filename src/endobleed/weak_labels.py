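"""HSV-threshold weak labels for red regions in endoscopic frames.

The weak-label stage turns an RGB endoscopic frame into a binary "red
region" mask with no learning involved: the frame is converted to HSV,
pixels falling inside fixed red hue/saturation/value bands are marked,
and a field-of-view (FOV) mask removes the black margins outside the
illuminated circular surgical field.  The fraction of FOV pixels that
are red (the red-area ratio) is used to filter out frames with only
insignificant red noise.

Hue is stored on the half-degree scale [0, 180) with 8-bit saturation
and value, the convention under which the threshold constants
(hue 0-8 and 172-180, saturation 90-255, value 50-255; FOV S > 60,
V > 70) are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image


class DegenerateFrameError(ValueError):
    """Raised when a frame has an empty field of view (e.g. all black)."""


class MaskFormatError(ValueError):
    """Raised when a mask file contains values other than {0, 255}."""


@dataclass(frozen=True)
class HSVImage:
    """HSV planes of an 8-bit RGB image.

    hue is in half-degrees [0, 180); saturation and value are 0-255.
    """

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        if not (self.hue.shape == self.saturation.shape == self.value.shape):
            raise ValueError("HSV planes must share one shape")


@dataclass(frozen=True)
class RedThresholds:
    """Inclusive HSV bands defining 'red' (bleeding, vessels, bone)."""

    hue_bands: tuple[tuple[int, int], ...] = ((0, 8), (172, 180))
    sat_range: tuple[int, int] = (90, 255)
    val_range: tuple[int, int] = (50, 255)

    def __post_init__(self) -> None:
        for lo, hi in self.hue_bands:
            if not (0 <= lo <= hi <= 180):
                raise ValueError(f"hue band [{lo},{hi}] outside [0,180]")
        for lo, hi in (self.sat_range, self.val_range):
            if not (0 <= lo <= hi <= 255):
                raise ValueError("sat/val range outside [0,255]")


@dataclass(frozen=True)
class FovThresholds:
    """Strict lower bounds defining the illuminated field of view."""

    sat_min: int = 60
    val_min: int = 70

    def __post_init__(self) -> None:
        if not (0 <= self.sat_min <= 255 and 0 <= self.val_min <= 255):
            raise ValueError("FOV thresholds outside [0,255]")


@dataclass
class LabeledPair:
    """An image with its weak-label mask and red-area ratio."""

    image: np.ndarray | str | Path
    mask: np.ndarray
    red_area_ratio: float
    source_id: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.red_area_ratio <= 1.0:
            raise ValueError("red_area_ratio must lie in [0,1]")


def _require_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {image.shape}")
    return image


def rgb_to_hsv(image: np.ndarray) -> HSVImage:
    """Convert an 8-bit RGB image to HSV on the 0-180 / 0-255 scale.

    Standard hexcone model: V = max channel, S = 255*(max-min)/max
    (0 for black), hue in degrees halved and rounded.  Achromatic
    pixels get hue 0 and saturation 0.
    """
    image = _require_rgb(image)
    rgb = image.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    diff = mx - mn

    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(mx > 0, diff / mx * 255.0, 0.0)
        hue_deg = np.zeros_like(mx)
        safe = np.where(diff > 0, diff, 1.0)
        hr = (60.0 * (g - b) / safe) % 360.0
        hg = 60.0 * (b - r) / safe + 120.0
        hb = 60.0 * (r - g) / safe + 240.0
        hue_deg = np.where(mx == r, hr, np.where(mx == g, hg, hb))
        hue_deg = np.where(diff == 0, 0.0, hue_deg)

    hue = np.round(hue_deg / 2.0).astype(np.uint8) % 180
    return HSVImage(
        hue=hue,
        saturation=np.round(sat).astype(np.uint8),
        value=np.round(mx).astype(np.uint8),
    )


def hsv_to_rgb(
    hue: np.ndarray, saturation: np.ndarray, value: np.ndarray
) -> np.ndarray:
    """Inverse hexcone conversion from the 0-180 / 0-255 scale to 8-bit RGB."""
    h = np.asarray(hue, dtype=np.float64) * 2.0 / 60.0  # sector in [0,6)
    s = np.asarray(saturation, dtype=np.float64) / 255.0
    v = np.asarray(value, dtype=np.float64)

    i = np.floor(h).astype(int) % 6
    f = h - np.floor(h)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))

    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    rgb = np.stack([r, g, b], axis=-1)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def red_mask(hsv: HSVImage, thr: RedThresholds | None = None) -> np.ndarray:
    """Pixels inside any red hue band with in-range saturation and value.

    All band bounds are inclusive; hue 180 is identified with 0.
    """
    thr = thr or RedThresholds()
    h = hsv.hue.astype(np.int32)
    in_hue = np.zeros(h.shape, dtype=bool)
    for lo, hi in thr.hue_bands:
        in_hue |= (h >= lo) & (h <= hi)
        if hi >= 180:  # wrap: 180 == 0
            in_hue |= h == 0
    s, v = hsv.saturation, hsv.value
    return (
        in_hue
        & (s >= thr.sat_range[0])
        & (s <= thr.sat_range[1])
        & (v >= thr.val_range[0])
        & (v <= thr.val_range[1])
    )


def fov_mask(hsv: HSVImage, thr: FovThresholds | None = None) -> np.ndarray:
    """Illuminated field of view: saturation and value strictly above bounds."""
    thr = thr or FovThresholds()
    return (hsv.saturation > thr.sat_min) & (hsv.value > thr.val_min)


def weak_label(
    image: np.ndarray,
    red_thr: RedThresholds | None = None,
    fov_thr: FovThresholds | None = None,
) -> tuple[np.ndarray, float]:
    """Red-region weak label of a frame and its red-area ratio within the FOV.

    Returns (mask, ratio) where mask = red_mask AND fov_mask and
    ratio = |mask| / |fov_mask|.

    Raises
    ------
    DegenerateFrameError
        If the FOV mask is empty (e.g. an all-black frame).
    """
    hsv = rgb_to_hsv(image)
    fov = fov_mask(hsv, fov_thr)
    n_fov = int(fov.sum())
    if n_fov == 0:
        raise DegenerateFrameError("empty field of view: frame has no illuminated pixels")
    mask = red_mask(hsv, red_thr) & fov
    return mask, float(mask.sum()) / n_fov


def filter_pairs(
    pairs: Sequence[LabeledPair],
    min_ratio: float = 0.01,
    inclusive: bool = False,
) -> list[LabeledPair]:
    """Keep pairs whose red-area ratio exceeds ``min_ratio``.

    The default reads "exceeding 1%" strictly; pass ``inclusive=True``
    to keep pairs at exactly the bound.  Order is preserved.
    """
    if inclusive:
        return [p for p in pairs if p.red_area_ratio >= min_ratio]
    return [p for p in pairs if p.red_area_ratio > min_ratio]


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit grayscale PNG with red regions white."""
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    Image.fromarray(mask.astype(np.uint8) * 255, mode="L").save(Path(path))


def read_mask(path: str | Path, tolerant: bool = False) -> np.ndarray:
    """Read an 8-bit mask PNG back to a boolean array.

    A pure mask file holds only 0 and 255.  With ``tolerant=True``
    intermediate values (e.g. from a lossy round trip) are binarized
    at >127 instead of raising :class:`MaskFormatError`.
    """
    arr = np.asarray(Image.open(Path(path)).convert("L"))
    impure = np.setdiff1d(np.unique(arr), [0, 255])
    if impure.size and not tolerant:
        raise MaskFormatError(
            f"{path}: mask holds values other than 0/255 (e.g. {impure[:5].tolist()})"
        )
    return arr > 127
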