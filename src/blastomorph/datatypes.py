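"""Shared domain types for blastocyst morphometry.

Coordinate convention used throughout the package: 0-based pixel indices,
``x`` = column, ``y`` = row.  Angles are in degrees, measured from the +x
(column) axis, and normalized to ``[0, 180)``.  A bounding-box width over an
inclusive pixel extent is ``max_col - min_col + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EllipseParams",
    "MaskFrame",
    "MorphometricResult",
    "SceneTruth",
    "IOUReport",
    "CovariateFit",
    "LogisticFitResult",
    "ROCResult",
]


@dataclass(frozen=True)
class EllipseParams:
    """Geometric ellipse parameters in pixel units.

    ``major_diameter`` is the long diameter (twice the semi-major axis);
    ``angle`` is the orientation of the major axis in degrees, stored in
    ``[0, 180)``.
    """

    center_x: float
    center_y: float
    major_diameter: float
    minor_diameter: float
    angle: float = 0.0

    def __post_init__(self) -> None:
        if not (self.minor_diameter > 0):
            raise ValueError("minor_diameter must be positive")
        if self.major_diameter < self.minor_diameter:
            raise ValueError(
                "major_diameter must be >= minor_diameter "
                f"(got {self.major_diameter} < {self.minor_diameter})"
            )
        object.__setattr__(self, "angle", float(self.angle) % 180.0)

    @property
    def semi_major(self) -> float:
        return self.major_diameter / 2.0

    @property
    def semi_minor(self) -> float:
        return self.minor_diameter / 2.0

    @property
    def aspect(self) -> float:
        """Elongation: major over minor diameter (1 = circle)."""
        return self.major_diameter / self.minor_diameter


@dataclass
class MaskFrame:
    """One time-lapse frame: binary TE and ICM rasters plus metadata.

    ``timestamp`` is in hours post pronuclear fading (tPNf = hour zero);
    ``scale`` is micrometres per pixel.
    """

    te_mask: np.ndarray
    icm_mask: np.ndarray
    timestamp: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.te_mask = np.asarray(self.te_mask, dtype=bool)
        self.icm_mask = np.asarray(self.icm_mask, dtype=bool)
        if self.te_mask.shape != self.icm_mask.shape:
            raise ValueError(
                "TE and ICM rasters must share identical dimensions: "
                f"{self.te_mask.shape} vs {self.icm_mask.shape}"
            )
        if not (self.scale > 0):
            raise ValueError("scale must be positive (um per pixel)")
        if self.timestamp < 0:
            raise ValueError("timestamp must be >= 0 hours post-tPNf")


@dataclass(frozen=True)
class MorphometricResult:
    """The four morphometric measurements for one embryo at one frame.

    ``blastocyst_size`` and ``icm_size`` are in micrometres; ``icm_ratio``
    is icm_size / blastocyst_size; ``icm_shape`` is the fitted-ellipse
    long/short diameter ratio (1 = round ICM, > 1 = elongated).
    """

    blastocyst_size: float
    icm_size: float
    icm_ratio: float
    icm_shape: float
    measurement_time: float

    def __post_init__(self) -> None:
        if self.icm_shape < 1.0 - 1e-12:
            raise ValueError("icm_shape must be >= 1")
        expected = self.icm_size / self.blastocyst_size
        if not np.isclose(self.icm_ratio, expected, rtol=1e-12, atol=1e-12):
            raise ValueError("icm_ratio must equal icm_size / blastocyst_size")


@dataclass(frozen=True)
class SceneTruth:
    """Ground-truth geometry of a synthetic embryo scene.

    Stands in for the expert hand-drawn segmentation: the TE ellipse traces
    the outer trophectoderm contour (zona pellucida excluded), the ICM
    ellipse the inner cell mass.  All lengths in pixels; ``scale`` converts
    to micrometres.
    """

    te_ellipse: EllipseParams
    icm_ellipse: EllipseParams
    scale: float
    image_width: int
    image_height: int
    timestamp: float = 85.98

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValueError("scale must be positive")
        if self.image_width < 1 or self.image_height < 1:
            raise ValueError("image dimensions must be positive")


@dataclass
class IOUReport:
    """Per-frame IOU values and threshold-exceedance fractions."""

    per_frame_iou: list[float]
    frac_above_50: float
    frac_above_75: float
    n_frames: int
    fractions: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.per_frame_iou) != self.n_frames:
            raise ValueError("per_frame_iou length must equal n_frames")
        if not (0.0 <= self.frac_above_75 <= self.frac_above_50 <= 1.0):
            raise ValueError("threshold fractions must be monotone in threshold")


@dataclass(frozen=True)
class CovariateFit:
    """Per-covariate summary of a logistic fit (log-odds scale and OR scale)."""

    name: str
    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LogisticFitResult:
    """Maximum-likelihood logistic regression fit.

    ``covariates`` holds one :class:`CovariateFit` per model term (the
    intercept is named ``const``).  Odds ratios are ``exp(coef)`` with Wald
    95% intervals ``exp(coef +/- 1.96 * se)``.
    """

    covariates: dict[str, CovariateFit]
    log_likelihood: float
    converged: bool
    n_iterations: int
    n_obs: int

    def __getitem__(self, name: str) -> CovariateFit:
        return self.covariates[name]

    def odds_ratio(self, name: str) -> float:
        return self.covariates[name].odds_ratio

    def to_dict(self) -> dict:
        return {
            "covariates": {
                k: {
                    "coef": v.coef,
                    "se": v.se,
                    "odds_ratio": v.odds_ratio,
                    "ci_low": v.ci_low,
                    "ci_high": v.ci_high,
                    "p_value": v.p_value,
                }
                for k, v in self.covariates.items()
            },
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "n_obs": self.n_obs,
        }


@dataclass(frozen=True)
class ROCResult:
    """AUC with DeLong standard error and Wald 95% interval."""

    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI must bracket the AUC")

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }
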