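"""Replicate statistics, cube-linear calibration and the pump-malfunction check.

The calibration model is a straight line between pump steps *s* and the
cube of the measured volume length *L*:

    L^3 = a * s + b

which is exact for an ideal conical tip (volume proportional to height
cubed, commanded volume proportional to steps).  Inverting the line gives
a real-valued step estimate from a single image measurement,

    s_hat = (L^3 - b) / a,

and a pump is flagged as malfunctioning when s_hat deviates from the
commanded step count beyond a configured bound.

``CubeLinearCalibrator`` is a scikit-learn style estimator (``fit`` /
``predict`` / ``get_params``); the module-level functions ``ols_fit``,
``fit_cube_linear``, ``estimate_steps`` and ``check_pump`` are thin
wrappers kept for scripting convenience.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class InsufficientReplicatesError(ValueError):
    """Standard deviation requested from a single replicate."""


class DegenerateDesignError(ValueError):
    """OLS requested with fewer than two distinct x values."""


@dataclass(frozen=True)
class ReplicateTable:
    """Replicate measurements keyed by pump steps.

    ``values[i]`` holds the replicates observed at ``steps[i]`` — either
    reagent mass (balance) or volume length in pixels (camera).
    """

    steps: np.ndarray
    values: list[np.ndarray]

    def __post_init__(self) -> None:
        steps = np.asarray(self.steps, dtype=float)
        if steps.ndim != 1 or len(steps) == 0:
            raise ValueError("steps must be a non-empty 1-D sequence")
        if np.any(steps <= 0):
            raise ValueError("pump steps must be strictly positive")
        if len(np.unique(steps)) != len(steps):
            raise ValueError("pump steps must be unique per row")
        if len(self.values) != len(steps):
            raise ValueError("one replicate group required per step level")
        for s, v in zip(steps, self.values):
            arr = np.asarray(v, dtype=float)
            if arr.size == 0:
                raise ValueError(f"no replicates at {s:g} steps")
            if np.any(arr <= 0):
                raise ValueError(f"non-positive measurement at {s:g} steps")
        object.__setattr__(self, "steps", steps)
        object.__setattr__(
            self, "values", [np.asarray(v, dtype=float) for v in self.values]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReplicateTable":
        """Build from a DataFrame with a ``steps`` column and either
        ``rep*`` replicate columns or a ``mean`` column (single replicate).
        Duplicate step levels are merged as extra replicates."""
        if "steps" not in df.columns:
            raise ValueError("replicate table needs a 'steps' column")
        rep_cols = [c for c in df.columns if c.lower().startswith("rep")]
        if not rep_cols:
            if "mean" not in df.columns:
                raise ValueError("replicate table needs rep* or 'mean' columns")
            rep_cols = ["mean"]
        grouped = df.groupby("steps", sort=True)
        steps, values = [], []
        for s, g in grouped:
            vals = g[rep_cols].to_numpy(dtype=float).ravel()
            vals = vals[~np.isnan(vals)]
            steps.append(float(s))
            values.append(vals)
        return cls(np.asarray(steps), values)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ReplicateTable":
        return cls.from_frame(pd.read_csv(path))

    def means(self) -> np.ndarray:
        return np.array([v.mean() for v in self.values])


def replicate_stats(table: ReplicateTable) -> pd.DataFrame:
    """Per-step mean, sample std (n-1) and CV in percent.

    Raises ``InsufficientReplicatesError`` if any step level has a single
    replicate, since the sample std is undefined there.
    """
    short = [s for s, v in zip(table.steps, table.values) if len(v) < 2]
    if short:
        raise InsufficientReplicatesError(
            f"std undefined with a single replicate at steps {short}"
        )
    rows = []
    for s, v in zip(table.steps, table.values):
        mean = v.mean()
        std = v.std(ddof=1)
        rows.append(
            {"steps": s, "mean": mean, "std": std, "cv_percent": 100.0 * std / mean}
        )
    return pd.DataFrame(rows)


def summary_stats(means: Sequence[float], stds: Sequence[float]) -> np.ndarray:
    """CV in percent from already-summarised mean/std columns."""
    means = np.asarray(means, dtype=float)
    stds = np.asarray(stds, dtype=float)
    return 100.0 * stds / means


def ols_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D sequences, n >= 2")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all x values identical; OLS slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


class CubeLinearCalibrator(RegressorMixin, BaseEstimator):
    """Calibrates cubed volume length against pump steps.

    Parameters
    ----------
    transform : {"cubed volume length", "mass"}
        Which response is fitted against pump steps.  The cube transform is
        the volume-length calibration; "mass" fits the response untransformed
        (used for gravimetric linearity checks).

    Attributes (after ``fit``)
    --------------------------
    slope_, intercept_ : float
        OLS line of the (transformed) response on steps.
    r_squared_ : float
        Coefficient of determination of that fit.
    """

    def __init__(self, transform: str = "cubed volume length"):
        self.transform = transform

    def _transform_y(self, y: np.ndarray) -> np.ndarray:
        if self.transform == "cubed volume length":
            return y**3
        if self.transform == "mass":
            return y
        raise ValueError(f"unknown transform {self.transform!r}")

    def fit(self, X, y=None) -> "CubeLinearCalibrator":
        """Fit on steps ``X`` (1-D or (n, 1)) and measurements ``y``, or on a
        :class:`ReplicateTable` (replicate means are used)."""
        if isinstance(X, ReplicateTable):
            y = X.means()
            X = X.steps
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        slope, intercept, r2 = ols_fit(X, self._transform_y(y))
        self.slope_ = slope
        self.intercept_ = intercept
        self.r_squared_ = r2
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        """Expected measurement at the given pump steps (inverse transform
        applied, so cubed-length models return lengths in pixels)."""
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        line = self.slope_ * X + self.intercept_
        if self.transform == "cubed volume length":
            return np.cbrt(line)
        return line

    def estimate_steps(self, volume_length) -> np.ndarray | float:
        """Invert the calibration: s_hat = (L^3 - b) / a.

        Negative estimates are returned as-is; they indicate a measurement
        below the calibrated range, not an arithmetic failure.
        """
        check_is_fitted(self)
        if self.transform != "cubed volume length":
            raise ValueError(
                "step estimation requires a 'cubed volume length' calibration"
            )
        if self.slope_ == 0:
            raise ZeroDivisionError("zero calibration slope; cannot invert")
        L = np.asarray(volume_length, dtype=float)
        est = (L**3 - self.intercept_) / self.slope_
        return float(est) if est.ndim == 0 else est

    def to_dict(self) -> dict:
        check_is_fitted(self)
        return {
            "slope": self.slope_,
            "intercept": self.intercept_,
            "r_squared": self.r_squared_,
            "transform": self.transform,
        }

    def save(self, path: str | Path, **extra) -> None:
        payload = {**self.to_dict(), **extra}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CubeLinearCalibrator":
        model = cls(transform=d.get("transform", "cubed volume length"))
        model.slope_ = float(d["slope"])
        model.intercept_ = float(d["intercept"])
        model.r_squared_ = float(d["r_squared"])
        model.n_features_in_ = 1
        return model

    @classmethod
    def load(cls, path: str | Path) -> "CubeLinearCalibrator":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_cube_linear(table: ReplicateTable) -> CubeLinearCalibrator:
    """OLS of cubed replicate-mean volume lengths on pump steps."""
    return CubeLinearCalibrator(transform="cubed volume length").fit(table)


def estimate_steps(volume_length, model: CubeLinearCalibrator):
    return model.estimate_steps(volume_length)


def deviation_stats(
    true_steps: float, replicate_estimates: Sequence[float]
) -> tuple[float, float]:
    """RMS deviation of step estimates measured from the *true* commanded
    steps (not the sample mean), and that deviation in percent of the true
    steps: (dev, rel_dev_percent)."""
    if true_steps <= 0:
        raise ValueError(f"true_steps must be positive, got {true_steps}")
    est = np.asarray(replicate_estimates, dtype=float)
    if est.size == 0:
        raise ValueError("at least one estimate required")
    dev = float(np.sqrt(np.mean((est - true_steps) ** 2)))
    return dev, 100.0 * dev / true_steps


@dataclass(frozen=True)
class PumpCheckResult:
    commanded_steps: float
    estimated_steps: float
    deviation: float  # estimated - commanded, signed
    relative_deviation_percent: float
    verdict: str  # "pass" | "fail"
    bound_mode: str  # "absolute" | "relative"
    bound_value: float

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"

    def to_dict(self) -> dict:
        return asdict(self)


def check_pump(
    commanded: float,
    measured_length: float,
    model: CubeLinearCalibrator,
    bound_mode: str = "relative",
    bound_value: float = 5.0,
) -> PumpCheckResult:
    """Flag pump malfunction when the step estimate deviates from the
    commanded steps beyond the bound (strict >); default bound is 5 %
    relative, the device inaccuracy specification."""
    if bound_value <= 0:
        raise ValueError(f"bound_value must be positive, got {bound_value}")
    if bound_mode not in ("absolute", "relative"):
        raise ValueError(f"bound_mode must be 'absolute' or 'relative', got {bound_mode!r}")
    check_is_fitted(model)
    est = float(model.estimate_steps(measured_length))
    deviation = est - commanded
    rel = 100.0 * abs(deviation) / commanded
    exceeded = abs(deviation) > bound_value if bound_mode == "absolute" else rel > bound_value
    return PumpCheckResult(
        commanded_steps=float(commanded),
        estimated_steps=est,
        deviation=deviation,
        relative_deviation_percent=rel,
        verdict="fail" if exceeded else "pass",
        bound_mode=bound_mode,
        bound_value=float(bound_value),
    )
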