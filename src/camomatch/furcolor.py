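"""Specimen (fur) coloration from standardized photographs.

A specimen photograph carries a white-reference patch (from a color
checker) and a usable-fur region on the animal's back. Processing is:
white-balance against the reference, then average RGB over a square
region of interest placed twice, independently and randomly, inside the
usable fur — the duplicate measurements feed the downstream repeatability
(ICC) analysis. Values are 8-bit RGB (0-255); luminosity is BT.601.

In the synthetic pipeline duplicate fur values are generated directly;
this image path exists for real photographs and is exercised on small
synthetic fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rscolor import rgb_luminosity

__all__ = ["SpecimenImage", "FurColor", "white_balance", "measure_fur", "random_roi",
           "measure_duplicates"]

Rect = tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open


def _rect_slices(rect: Rect) -> tuple[slice, slice]:
    r0, r1, c0, c1 = rect
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"empty rectangle {rect}")
    return slice(r0, r1), slice(c0, c1)


def _overlaps(a: Rect, b: Rect) -> bool:
    return a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]


@dataclass
class SpecimenImage:
    """RGB photograph with a white-reference patch and a usable-fur region.

    ``excluded`` rectangles mark fur that must not be sampled (dark fur
    near the tail, lighter flank fur). The condition flag records whether
    the specimen was clean enough to measure at all.
    """

    rgb: np.ndarray  # (rows, cols, 3) float or uint8, 0-255
    white_region: Rect
    fur_region: Rect
    excluded: tuple[Rect, ...] = ()
    suitable_condition: bool = True

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, float)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be (rows, cols, 3)")
        _rect_slices(self.white_region)
        _rect_slices(self.fur_region)
        if _overlaps(self.white_region, self.fur_region):
            raise ValueError("white reference and fur regions must be disjoint")


@dataclass
class FurColor:
    """One square-ROI fur measurement (two per specimen)."""

    r: float
    g: float
    b: float
    luminosity: float
    roi_area_px: int
    measurement: int  # 1 or 2


def white_balance(
    image: SpecimenImage, target_white: float = 255.0
) -> tuple[SpecimenImage, float]:
    """Scale each channel so the white patch means hit ``target_white``.

    Returns the corrected image and the fraction of channel values that
    had to be clipped at 255.
    """
    rs, cs = _rect_slices(image.white_region)
    ref = image.rgb[rs, cs].reshape(-1, 3).mean(axis=0)
    if np.any(ref <= 0):
        raise ValueError("white reference patch has a zero channel mean")
    scaled = image.rgb * (target_white / ref)
    clip_fraction = float((scaled > 255.0).mean())
    corrected = SpecimenImage(
        rgb=np.clip(scaled, 0.0, 255.0),
        white_region=image.white_region,
        fur_region=image.fur_region,
        excluded=image.excluded,
        suitable_condition=image.suitable_condition,
    )
    return corrected, clip_fraction


def measure_fur(image: SpecimenImage, roi: Rect, measurement: int = 1) -> FurColor:
    """Channel means and BT.601 luminosity over a square fur ROI.

    The ROI must be square, lie inside the usable-fur region and avoid
    every excluded rectangle.
    """
    if not image.suitable_condition:
        raise ValueError("specimen flagged as unsuitable (dusty/damaged)")
    r0, r1, c0, c1 = roi
    if (r1 - r0) != (c1 - c0):
        raise ValueError("ROI must be square")
    fr0, fr1, fc0, fc1 = image.fur_region
    if not (fr0 <= r0 and r1 <= fr1 and fc0 <= c0 and c1 <= fc1):
        raise ValueError("ROI outside the usable-fur region")
    for ex in image.excluded:
        if _overlaps(roi, ex):
            raise ValueError(f"ROI overlaps excluded area {ex}")
    rs, cs = _rect_slices(roi)
    patch = image.rgb[rs, cs].reshape(-1, 3)
    r, g, b = patch.mean(axis=0)
    return FurColor(
        r=float(r),
        g=float(g),
        b=float(b),
        luminosity=float(rgb_luminosity(r, g, b)),
        roi_area_px=patch.shape[0],
        measurement=measurement,
    )


def random_roi(
    image: SpecimenImage,
    side_px: int,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> Rect:
    """Uniform-random square ROI inside the fur region, avoiding exclusions.

    The side is shrunk (halved, down to 2 px) only if no placement of the
    requested size exists after ``max_tries`` rejection-sampling attempts.
    """
    fr0, fr1, fc0, fc1 = image.fur_region
    side = min(side_px, fr1 - fr0, fc1 - fc0)
    while side >= 2:
        for _ in range(max_tries):
            r0 = int(rng.integers(fr0, fr1 - side + 1))
            c0 = int(rng.integers(fc0, fc1 - side + 1))
            roi = (r0, r0 + side, c0, c0 + side)
            if not any(_overlaps(roi, ex) for ex in image.excluded):
                return roi
        side //= 2
    raise ValueError("could not place an ROI inside the usable-fur region")


def measure_duplicates(
    image: SpecimenImage, side_px: int, seed: int
) -> tuple[FurColor, FurColor]:
    """The standard protocol: two independent random square measurements."""
    rng = np.random.default_rng(seed)
    first = measure_fur(image, random_roi(image, side_px, rng), measurement=1)
    second = measure_fur(image, random_roi(image, side_px, rng), measurement=2)
    return first, second
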