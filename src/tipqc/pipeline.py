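"""The image-to-measurement pipeline as a scikit-learn style transformer."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import projection, raster
from .raster import RoiSpec


@dataclass(frozen=True)
class Measurement:
    """Scalar measurements extracted from one frame."""

    volume_length_px: int
    tip_column: int | None  # None = tip absent
    holder_row: int | None  # None = holder absent


class ReagentSegmenter(TransformerMixin, BaseEstimator):
    """Segments the red reagent column inside the tip ROI of an RGB frame.

    Stateless (``fit`` only validates parameters): the ROI and threshold are
    fixed device configuration, not learned from data.  ``transform`` maps an
    RGB image — or a list of them — to the binary reagent mask produced by
    the crop / pure-red / median / fixed-threshold chain.

    Parameters
    ----------
    roi : RoiSpec or None
        Tip region; ``None`` segments the full frame.
    threshold : int
        Fixed binarization threshold on the red-minus-luminance channel.
        Default 40: matte backgrounds sit near 0 and red reagent well above
        100 on that channel, so the margin is wide either way.
    invert_red : bool
        Use luminance-minus-red instead (opposite sign convention).
    median : bool
        Apply the 3x3 median despeckle before thresholding.
    """

    def __init__(
        self,
        roi: RoiSpec | None = None,
        threshold: int = 40,
        invert_red: bool = False,
        median: bool = True,
    ):
        self.roi = roi
        self.threshold = threshold
        self.invert_red = invert_red
        self.median = median

    def fit(self, X=None, y=None) -> "ReagentSegmenter":
        if not 0 <= self.threshold <= 255:
            raise ValueError(f"threshold must be in [0, 255], got {self.threshold}")
        return self

    def transform(self, X):
        self.fit()
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return self._segment(X)
        return [self._segment(img) for img in X]

    def _segment(self, img: np.ndarray) -> np.ndarray:
        return raster.segment_reagent(
            img,
            roi=self.roi,
            threshold=self.threshold,
            invert_red=self.invert_red,
            median=self.median,
        )


def measure_image(
    img: np.ndarray,
    tip_roi: RoiSpec | None = None,
    holder_roi: RoiSpec | None = None,
    threshold: int = 40,
    holder_threshold: int = 100,
    *,
    invert_red: bool = False,
) -> Measurement:
    """Run the full measurement chain on one RGB frame.

    The reagent mask (tip ROI) yields the volume length and the tip centre
    column; the holder mask (holder ROI, dark-object binarization of the
    luminance) yields the holder top row.  Tip-ROI column indices are
    reported in full-frame coordinates so they are comparable across ROIs.
    """
    mask = ReagentSegmenter(
        roi=tip_roi, threshold=threshold, invert_red=invert_red
    ).transform(img)
    vlen = projection.volume_length(mask)
    tip_col = projection.tip_position(mask)
    if tip_col is not None and tip_roi is not None:
        tip_col += tip_roi.left_col

    holder_row = None
    if holder_roi is not None:
        sub = raster.crop_roi(img, holder_roi)
        holder_mask = raster.binarize_below(raster.luminance(sub), holder_threshold)
        holder_row = projection.holder_top(holder_mask)
        if holder_row is not None:
            holder_row += holder_roi.top_row
    return Measurement(vlen, tip_col, holder_row)
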