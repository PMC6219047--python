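"""Pixel-level preprocessing: ROI cropping, luminance, pure-red extraction,
median filtering and fixed-threshold binarization.

The chain ``crop_roi -> pure_red -> median3x3 -> binarize`` turns an RGB
frame of a reagent-loaded pipette tip into a binary mask of the reagent
column.  Red reagent on a matte grey background separates cleanly in the
``R - Y`` channel (Y = BT.601 luminance), so a single fixed threshold is
sufficient under the controlled illumination of the device.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

# ITU-R BT.601 luma weights for 8-bit RGB
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class RoiSpec:
    """Axis-aligned region of interest, 0-based, half-open on bottom/right.

    The camera and tip holder are rigidly mounted, so the ROI is a fixed
    property of the device configuration rather than something detected
    per frame.
    """

    top_row: int
    bottom_row: int
    left_col: int
    right_col: int

    def __post_init__(self) -> None:
        if self.top_row >= self.bottom_row:
            raise ValueError(
                f"empty ROI rows: top_row={self.top_row} must be < "
                f"bottom_row={self.bottom_row}"
            )
        if self.left_col >= self.right_col:
            raise ValueError(
                f"empty ROI columns: left_col={self.left_col} must be < "
                f"right_col={self.right_col}"
            )
        if self.top_row < 0 or self.left_col < 0:
            raise ValueError("ROI indices must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.bottom_row - self.top_row, self.right_col - self.left_col)


def _as_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (1, 3):
        return arr
    raise ValueError(f"expected a 2-D or HxWx3 image, got shape {arr.shape}")


def _require_rgb(img: np.ndarray, op: str) -> np.ndarray:
    arr = _as_image(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{op} requires a 3-channel RGB image, got shape {arr.shape}")
    return arr


def _require_gray(img: np.ndarray, op: str) -> np.ndarray:
    arr = _as_image(img)
    if arr.ndim == 3:
        if arr.shape[2] != 1:
            raise ValueError(f"{op} requires a single-channel image, got shape {arr.shape}")
        arr = arr[:, :, 0]
    return arr


def crop_roi(img: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Extract the ROI sub-image; raises if any edge falls outside the frame."""
    arr = _as_image(img)
    h, w = arr.shape[:2]
    if roi.bottom_row > h:
        raise ValueError(f"ROI bottom_row={roi.bottom_row} exceeds image height {h}")
    if roi.right_col > w:
        raise ValueError(f"ROI right_col={roi.right_col} exceeds image width {w}")
    return arr[roi.top_row : roi.bottom_row, roi.left_col : roi.right_col].copy()


def luminance(img: np.ndarray) -> np.ndarray:
    """BT.601 luminance Y = 0.299 R + 0.587 G + 0.114 B, rounded half-up to uint8."""
    rgb = _require_rgb(img, "luminance")
    y = rgb.astype(np.float64) @ _LUMA_WEIGHTS
    # round half-up so e.g. 76.5 -> 77, matching fixed-point sensor pipelines
    return np.clip(np.floor(y + 0.5), 0, 255).astype(np.uint8)


def pure_red(img: np.ndarray, *, invert: bool = False) -> np.ndarray:
    """Red-minus-luminance channel, clamped at zero.

    High inside red reagent, near zero on any grey surface (where R = Y).
    ``invert=True`` computes Y - R instead, the opposite sign convention,
    for devices whose reagent is darker than its luminance.
    """
    rgb = _require_rgb(img, "pure_red")
    r = rgb[:, :, 0].astype(np.int16)
    y = luminance(rgb).astype(np.int16)
    diff = y - r if invert else r - y
    return np.clip(diff, 0, 255).astype(np.uint8)


def median3x3(img: np.ndarray) -> np.ndarray:
    """3x3 median filter with edge replication; shape-preserving."""
    gray = _require_gray(img, "median3x3")
    return ndimage.median_filter(gray, size=3, mode="nearest")


def binarize(img: np.ndarray, threshold: int) -> np.ndarray:
    """Fixed-threshold binarization: 1 iff pixel > threshold (strict)."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    gray = _require_gray(img, "binarize")
    return (gray > threshold).astype(np.uint8)


def binarize_below(img: np.ndarray, threshold: int) -> np.ndarray:
    """Dark-object binarization: 1 iff pixel < threshold (strict).

    Used for the tip holder, which is dark against the matte background.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    gray = _require_gray(img, "binarize_below")
    return (gray < threshold).astype(np.uint8)


def segment_reagent(
    img: np.ndarray,
    roi: RoiSpec | None = None,
    threshold: int = 40,
    *,
    invert_red: bool = False,
    median: bool = True,
) -> np.ndarray:
    """Full segmentation chain: crop -> pure_red -> median3x3 -> binarize."""
    arr = _require_rgb(img, "segment_reagent")
    if roi is not None:
        arr = crop_roi(arr, roi)
    p = pure_red(arr, invert=invert_red)
    if median:
        p = median3x3(p)
    return binarize(p, threshold)
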