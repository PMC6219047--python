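"""Pipeline configuration: ROIs, thresholds, calibration path and bounds.

Loaded from a TOML file; individual CLI flags override file values.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .raster import RoiSpec


@dataclass
class PipelineConfig:
    tip_roi: RoiSpec | None = None
    holder_roi: RoiSpec | None = None
    threshold: int = 40
    holder_threshold: int = 100
    invert_red: bool = False
    calibration_path: str | None = None
    bound_mode: str = "relative"
    bound_value: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError(f"threshold must be in [0, 255], got {self.threshold}")
        if not 0 <= self.holder_threshold <= 255:
            raise ValueError(
                f"holder_threshold must be in [0, 255], got {self.holder_threshold}"
            )
        if self.bound_value <= 0:
            raise ValueError(f"bound_value must be positive, got {self.bound_value}")
        if self.bound_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown bound_mode {self.bound_mode!r}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        kwargs: dict = {}
        for key in ("tip_roi", "holder_roi"):
            if key in raw:
                r = raw[key]
                kwargs[key] = RoiSpec(r["top_row"], r["bottom_row"], r["left_col"], r["right_col"])
        for key in (
            "threshold",
            "holder_threshold",
            "invert_red",
            "calibration_path",
            "bound_mode",
            "bound_value",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)
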