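"""Synthetic tip-camera scenes with exact ground truth.

Renders the imaging geometry of a reagent-loaded conical pipette tip seen
by a rigidly mounted camera: an upright cone (apex at the bottom) partly
filled with red liquid, grey translucent-looking walls, a dark tip holder
above, a matte grey background, an optional vertical illumination ramp and
additive Gaussian sensor noise.  Because the liquid body is an ideal cone,
the column height follows the exact cube law

    h = (3 V / (pi tan^2 theta))^(1/3) * scale,

so rendered scenes carry a known mapping from commanded volume (or pump
steps) to the number of image rows the liquid occupies — the ground truth
every pipeline stage is tested against.

The defaults place a 640-step aspiration at a column of about 260 rows in
a 360x160 frame, i.e. the same working range as a real tip filling most of
the camera's field of view.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .raster import RoiSpec


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of one synthetic frame.

    Liquid volume may be given directly (``volume``, arbitrary cubic
    units) or as ``steps`` pump steps at ``volume_per_step`` units each.
    ``px_per_unit`` scales cube-root-of-volume to pixels.
    """

    height: int = 360
    width: int = 160
    apex_row: int = 340
    apex_col: int = 80
    half_angle_deg: float = 10.0
    tip_length_px: int = 280
    wall_color: tuple[int, int, int] = (120, 120, 125)
    liquid_color: tuple[int, int, int] = (180, 30, 30)
    background_color: tuple[int, int, int] = (200, 200, 200)
    holder_color: tuple[int, int, int] = (60, 60, 60)
    holder_top_row: int = 10
    holder_height: int = 30
    holder_half_width: int = 30
    volume: float | None = None
    steps: float | None = None
    volume_per_step: float = 900.0
    px_per_unit: float = 1.0
    gradient: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0
    tip_present: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.half_angle_deg < 45.0):
            raise ValueError(
                f"cone half-angle must be in (0, 45) degrees, got {self.half_angle_deg}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.effective_volume < 0:
            raise ValueError("liquid volume must be non-negative")
        if not (0 < self.apex_row < self.height - 1) or not (
            0 < self.apex_col < self.width - 1
        ):
            raise ValueError(
                f"tip apex ({self.apex_row}, {self.apex_col}) must lie strictly "
                f"inside the {self.height}x{self.width} frame"
            )

    @property
    def effective_volume(self) -> float:
        if self.volume is not None:
            return float(self.volume)
        if self.steps is not None:
            return float(self.steps) * self.volume_per_step
        return 0.0

    def default_tip_roi(self) -> RoiSpec:
        top = max(0, self.apex_row - self.tip_length_px - 10)
        return RoiSpec(top, min(self.height, self.apex_row + 3), 2, self.width - 2)

    def default_holder_roi(self) -> RoiSpec:
        return RoiSpec(0, self.holder_top_row + self.holder_height + 5, 0, self.width)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GroundTruth:
    """Geometry actually drawn, for oracle comparisons.

    ``volume_length_px = apex_row - liquid_top_row + 1`` whenever liquid was
    drawn, 0 otherwise; position fields are ``None`` for absent objects.
    """

    liquid_top_row: int | None
    apex_row: int
    column_height_px: float
    volume_length_px: int
    tip_center_col: int | None
    holder_top_row: int
    liquid_mask: np.ndarray = field(repr=False, compare=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("liquid_mask")  # per-pixel; sidecars carry scalars only
        return d


def height_from_volume(
    volume: float, half_angle_deg: float, px_per_unit: float = 1.0
) -> float:
    """Column height of a cone of the given volume: exact cube-root law."""
    if half_angle_deg <= 0:
        raise ValueError(f"half-angle must be positive, got {half_angle_deg}")
    if volume < 0:
        raise ValueError("volume must be non-negative")
    if volume == 0:
        return 0.0
    tan2 = math.tan(math.radians(half_angle_deg)) ** 2
    return px_per_unit * (3.0 * volume / (math.pi * tan2)) ** (1.0 / 3.0)


def render(scene: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Draw the scene; deterministic for a fixed ``scene.seed``."""
    h, w = scene.height, scene.width
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = scene.background_color
    liquid_mask = np.zeros((h, w), dtype=np.uint8)
    tan = math.tan(math.radians(scene.half_angle_deg))

    n_rows = 0
    liquid_top = None
    col_height = 0.0
    if scene.tip_present:
        vol = scene.effective_volume
        col_height = height_from_volume(vol, scene.half_angle_deg, scene.px_per_unit)
        n_rows = int(round(col_height))
        if vol > 0 and n_rows == 0:
            n_rows = 1
        if n_rows > scene.tip_length_px:
            raise ValueError(
                f"liquid column of {n_rows} rows exceeds the {scene.tip_length_px}-row tip"
            )
        # tip walls: 2-px-thick cone outline from the apex up
        for r in range(scene.apex_row - scene.tip_length_px, scene.apex_row + 1):
            d = scene.apex_row - r
            hw = int(math.floor(d * tan))
            for side in (-1, 1):
                lo = scene.apex_col + side * (hw + 1)
                hi = scene.apex_col + side * (hw + 2)
                c0, c1 = max(0, min(lo, hi)), min(w - 1, max(lo, hi))
                img[r, c0 : c1 + 1] = scene.wall_color
        if n_rows > 0:
            liquid_top = scene.apex_row - n_rows + 1
            for r in range(liquid_top, scene.apex_row + 1):
                # min half-width 1: a real apex images wider than a point
                # (optical blur, wall contact), and a 1-px spike would be
                # eaten by the 3x3 median downstream
                hw = max(1, int(math.floor((scene.apex_row - r) * tan)))
                c0 = max(0, scene.apex_col - hw)
                c1 = min(w - 1, scene.apex_col + hw)
                img[r, c0 : c1 + 1] = scene.liquid_color
                liquid_mask[r, c0 : c1 + 1] = 1

    hr0 = scene.holder_top_row
    img[
        hr0 : hr0 + scene.holder_height,
        max(0, scene.apex_col - scene.holder_half_width) : scene.apex_col
        + scene.holder_half_width
        + 1,
    ] = scene.holder_color

    if scene.gradient != 0.0:
        ramp = scene.gradient * (np.arange(h) / (h - 1) - 0.5)
        img += ramp[:, None, None]
    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        img += rng.normal(0.0, scene.noise_sigma, size=img.shape)

    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = GroundTruth(
        liquid_top_row=liquid_top,
        apex_row=scene.apex_row,
        column_height_px=col_height,
        volume_length_px=n_rows,
        tip_center_col=scene.apex_col if scene.tip_present else None,
        holder_top_row=hr0,
        liquid_mask=liquid_mask,
    )
    return img, truth


def sweep(
    volumes, scene: SceneSpec | None = None, seed: int = 0
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Render one scene per volume with per-element seeds derived from the
    master seed, so every element is individually reproducible."""
    volumes = list(volumes)
    if not volumes:
        raise ValueError("sweep requires at least one volume")
    if scene is None:
        scene = SceneSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(len(volumes))
    out = []
    for v, s in zip(volumes, child_seeds):
        spec = dataclasses.replace(scene, volume=float(v), steps=None, seed=int(s) % 2**31)
        out.append(render(spec))
    return out


def steps_sweep(
    steps, scene: SceneSpec | None = None, seed: int = 0
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Sweep expressed in pump steps via the scene's volume-per-step factor."""
    if scene is None:
        scene = SceneSpec()
    return sweep([float(s) * scene.volume_per_step for s in steps], scene, seed)


def inject_failure(
    scene: SceneSpec,
    mode: str,
    fraction: float | None = None,
    offset: int = 12,
) -> SceneSpec:
    """Derive a malfunction variant of a nominal scene.

    Modes: ``tip_absent`` (no tip, no liquid), ``holder_misaligned`` (tip
    centre shifted by ``offset`` columns), ``under_aspiration`` (liquid
    volume scaled by ``fraction`` in (0, 1) while the commanded steps stay).
    """
    if mode == "tip_absent":
        return dataclasses.replace(scene, tip_present=False, volume=0.0, steps=None)
    if mode == "holder_misaligned":
        return dataclasses.replace(scene, apex_col=scene.apex_col + offset)
    if mode == "under_aspiration":
        if fraction is None or not (0.0 < fraction < 1.0):
            raise ValueError(
                f"under_aspiration fraction must be in (0, 1), got {fraction}"
            )
        return dataclasses.replace(
            scene, volume=scene.effective_volume * fraction, steps=None
        )
    raise ValueError(f"unknown failure mode {mode!r}")
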