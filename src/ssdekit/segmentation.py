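"""Patient-body extraction from axial HU images.

A fixed HU threshold separates tissue from air, the CT table is removed by
keeping only the largest 8-connected component, and internal air (lungs,
bowel gas) is filled so the region of interest covers the full body
cross-section. The resulting mask feeds the area and mean-CT-number inputs
of the water-equivalent-diameter computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["BodyMask", "ROIStats", "SegConfig", "segment_body", "roi_stats"]

DEFAULT_THRESHOLD_HU = -900.0

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


class EmptyBodyError(ValueError):
    """No pixel above the body threshold."""


@dataclass(frozen=True)
class SegConfig:
    """Segmentation options shared by all per-slice dose computations."""

    threshold_hu: float = DEFAULT_THRESHOLD_HU
    fill_holes: bool = True
    skip_bad_slices: bool = False


@dataclass
class BodyMask:
    """Boolean body mask (True = patient, internal air included)."""

    mask: np.ndarray
    pixel_area: float  # cm^2 per pixel

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.mask.any():
            raise EmptyBodyError("body mask is empty")
        if not self.pixel_area > 0:
            raise ValueError("pixel_area must be positive")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class ROIStats:
    """Area and mean CT number over the body region of interest."""

    area_cm2: float
    mean_hu: float
    pixel_count: int


def segment_body(
    image: np.ndarray,
    pixel_spacing: tuple[float, float],
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    *,
    fill_holes: bool = True,
) -> BodyMask:
    """Extract the patient body from an axial HU image.

    Pixels strictly above ``threshold_hu`` are foreground; of the
    8-connected components only the largest (by pixel count) survives,
    which removes the CT table; enclosed holes are then filled (switchable)
    so internal air counts toward the cross-section.

    Parameters
    ----------
    image : 2D array of HU.
    pixel_spacing : (row, col) spacing in mm/pixel.
    threshold_hu : body/air threshold, must lie in (-1000, 0).
    fill_holes : include enclosed air in the mask (default True).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if not (-1000.0 < threshold_hu < 0.0):
        raise ValueError("threshold_hu must lie in (-1000, 0)")

    foreground = image > threshold_hu
    if not foreground.any():
        raise EmptyBodyError("no pixel above threshold; image is all air")

    labels, n_labels = ndimage.label(foreground, structure=_EIGHT_CONNECTED)
    counts = np.bincount(labels.ravel())[1:]  # skip background label 0
    best = int(np.argmax(counts)) + 1
    ties = np.flatnonzero(counts == counts[best - 1]) + 1
    if len(ties) > 1:
        # deterministic tie rule: component containing the earliest pixel
        # in row-major order
        order = labels.ravel()
        first = {int(lab): int(np.argmax(order == lab)) for lab in ties}
        best = min(first, key=first.get)
        warnings.warn(
            f"{len(ties)} components tie for largest; keeping the one with "
            "the smallest (row, col) origin", stacklevel=2)

    mask = labels == best
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)

    if mask[-1, :].any():
        warnings.warn(
            "body mask touches the lower image border; table contact or "
            "FOV truncation suspected", stacklevel=2)
    elif mask[0, :].any() or mask[:, 0].any() or mask[:, -1].any():
        warnings.warn("body mask touches the image border (FOV truncation)",
                      stacklevel=2)

    pixel_area = float(pixel_spacing[0]) * float(pixel_spacing[1]) / 100.0
    return BodyMask(mask=mask, pixel_area=pixel_area)


def roi_stats(image: np.ndarray, body: BodyMask) -> ROIStats:
    """Area (cm^2) and mean HU of the image over the body mask."""
    image = np.asarray(image, dtype=float)
    if image.shape != body.mask.shape:
        raise ValueError(
            f"image shape {image.shape} != mask shape {body.mask.shape}")
    count = body.pixel_count
    if count == 0:
        raise EmptyBodyError("body mask is empty")
    mean_hu = float(image[body.mask].mean())
    if mean_hu < -1000.0:
        warnings.warn(f"mean HU {mean_hu:.1f} below -1000 is unphysical",
                      stacklevel=2)
    return ROIStats(
        area_cm2=count * body.pixel_area,
        mean_hu=mean_hu,
        pixel_count=count,
    )
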