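"""Projection-profile analysis of binary masks.

A profile collapses the mask along one axis into per-row (or per-column)
foreground counts.  The *support* of a profile is the set of positions with
non-zero counts.  Three device quantities derive from supports:

* volume length — support length of the row profile of the reagent mask;
  the reagent volume is proportional to its cube (conical tip);
* tip position — centre of the column-profile support of the tip mask;
* holder top — first non-zero row of the holder mask's row profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ProjectionProfile:
    counts: np.ndarray  # non-negative ints, one per collapsed position
    axis: str  # "row": counts indexed by row; "column": by column

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class SupportStats:
    """Support of a profile: count of non-zero positions plus its extremes.

    ``first_nonzero``/``last_nonzero``/``center`` are None for an all-zero
    profile (an absent object is a detection outcome, not an error).
    Support length counts *all* non-zero positions, not the first-to-last
    span, so interior gaps reduce it.
    """

    support_length: int
    first_nonzero: int | None
    last_nonzero: int | None
    center: int | None

    @property
    def absent(self) -> bool:
        return self.support_length == 0


def _as_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D binary mask, got shape {arr.shape}")
    return arr != 0


def row_profile(mask: np.ndarray) -> ProjectionProfile:
    """Foreground count per row (the horizontal projection of the mask)."""
    return ProjectionProfile(_as_mask(mask).sum(axis=1).astype(np.int64), "row")


def column_profile(mask: np.ndarray) -> ProjectionProfile:
    """Foreground count per column."""
    return ProjectionProfile(_as_mask(mask).sum(axis=0).astype(np.int64), "column")


def support_stats(profile: ProjectionProfile) -> SupportStats:
    counts = np.asarray(profile.counts)
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        return SupportStats(0, None, None, None)
    first, last = int(nz[0]), int(nz[-1])
    return SupportStats(int(nz.size), first, last, (first + last) // 2)


def volume_length(mask: np.ndarray) -> int:
    """Number of rows intersecting the reagent column; 0 for an empty tip."""
    return support_stats(row_profile(mask)).support_length


def tip_position(mask: np.ndarray) -> int | None:
    """Column of the tip centre, or None when no tip is detected."""
    return support_stats(column_profile(mask)).center


def holder_top(mask: np.ndarray) -> int | None:
    """Topmost row of the holder, or None when no holder is detected."""
    return support_stats(row_profile(mask)).first_nonzero
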