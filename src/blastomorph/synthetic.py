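"""Synthetic embryo scenes and simulated implantation cohorts.

Clinical time-lapse data with known implantation outcomes are proprietary,
so every downstream stage of the pipeline is exercised on synthetic inputs
with known ground truth: rendered elliptical trophectoderm (TE) and inner
cell mass (ICM) masks, and cohorts whose covariate moments and logistic
effect structure follow the published study population (blastocyst size
147 +/- 19.1 um, ICM size 77 +/- 12.5 um, maternal age 33.5 y on 19-45,
~32.9% implantation).

Everything is a pure function of ``(config, seed)``: identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from skimage.morphology import dilation, disk, erosion

from .datatypes import EllipseParams, MaskFrame, SceneTruth
from .geometry import (
    ellipse_bbox_dims,
    ellipse_inside_ellipse,
    ellipse_inside_image,
    points_in_ellipse,
)

__all__ = [
    "CohortGenConfig",
    "PrevalenceSolveError",
    "generate_cohort",
    "render_embryo_masks",
    "perturb_mask",
    "sample_scene",
    "COHORT_COLUMNS",
]

#: Canonical cohort CSV schema (implantation outcome kid: KIDp=1 / KIDn=0).
COHORT_COLUMNS = [
    "embryo_id",
    "woman_age_years",
    "blastocyst_size_um",
    "icm_size_um",
    "icm_ratio",
    "icm_shape",
    "kid",
]

#: Mean interval from pronuclear fading to expanded blastocyst, hours.
DEFAULT_MEASUREMENT_OFFSET_H = 85.98


class PrevalenceSolveError(RuntimeError):
    """Raised when no intercept reproduces the requested prevalence."""


@dataclass(frozen=True)
class CohortGenConfig:
    """Generating distribution for a simulated transfer cohort.

    Covariate moments default to the study population: blastocyst size
    ~ N(147, 19.1) um, ICM size ~ N(77, 12.5) um (floored at 1 um), ICM
    shape ~ N(1.41, 0.32) truncated at 1, maternal age ~ N(33.5, 6.2)
    truncated to [19, 45] years by rejection.  Age and the morphometrics are
    generated independently of one another; the ICM-to-blastocyst ratio is
    derived, never sampled.

    The implantation outcome is Bernoulli with

        logit p = intercept + beta_size * size + beta_age * age
                  + beta_icm * icm + beta_size_above_mean * 1[size > mean(size)]

    where the indicator uses the realized cohort mean.  When
    ``target_prevalence`` is set, ``intercept`` is ignored and solved
    numerically so the expected prevalence over the realized covariates hits
    the target.
    """

    n_embryos: int
    seed: int
    size_mean: float = 147.0
    size_sd: float = 19.1
    icm_mean: float = 77.0
    icm_sd: float = 12.5
    icm_floor: float = 1.0
    shape_mean: float = 1.41
    shape_sd: float = 0.32
    age_mean: float = 33.5
    age_sd: float = 6.2
    age_min: float = 19.0
    age_max: float = 45.0
    beta_size: float = 0.0
    beta_age: float = 0.0
    beta_icm: float = 0.0
    beta_size_above_mean: float = 0.0
    intercept: float = 0.0
    target_prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")
        for name in ("size_sd", "icm_sd", "shape_sd", "age_sd"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if not (self.age_min < self.age_max):
            raise ValueError("age_min must be < age_max")
        if self.target_prevalence is not None and not (
            0.0 < self.target_prevalence < 1.0
        ):
            raise ValueError("target_prevalence must lie in (0, 1)")

    def replace(self, **changes) -> "CohortGenConfig":
        return dataclasses.replace(self, **changes)


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, low: float, high: float
) -> np.ndarray:
    """Rejection-sample N(mean, sd) restricted to [low, high]."""
    out = rng.normal(mean, sd, size=n)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + eta)) == target, by bracketed root find."""

    def gap(c: float) -> float:
        return float(np.mean(expit(c + eta))) - target

    lo, hi = -60.0, 60.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise PrevalenceSolveError(
            f"no intercept in [{lo}, {hi}] attains prevalence {target}; "
            "check the effect sizes and covariate scales"
        )
    return float(brentq(gap, lo, hi, xtol=1e-12))


def generate_cohort(config: CohortGenConfig) -> pd.DataFrame:
    """Simulate a transfer cohort; one row per embryo, ``COHORT_COLUMNS`` schema."""
    rng = np.random.default_rng(config.seed)
    n = config.n_embryos

    size = rng.normal(config.size_mean, config.size_sd, size=n)
    icm = _truncated_normal(
        rng, n, config.icm_mean, config.icm_sd, config.icm_floor, np.inf
    )
    shape = _truncated_normal(rng, n, config.shape_mean, config.shape_sd, 1.0, np.inf)
    age = _truncated_normal(
        rng, n, config.age_mean, config.age_sd, config.age_min, config.age_max
    )

    above_mean = (size > size.mean()).astype(float)
    eta = (
        config.beta_size * size
        + config.beta_age * age
        + config.beta_icm * icm
        + config.beta_size_above_mean * above_mean
    )
    if config.target_prevalence is not None:
        intercept = _solve_intercept(eta, config.target_prevalence)
    else:
        intercept = config.intercept
    kid = rng.binomial(1, expit(intercept + eta))

    return pd.DataFrame(
        {
            "embryo_id": [f"E{i:05d}" for i in range(n)],
            "woman_age_years": age,
            "blastocyst_size_um": size,
            "icm_size_um": icm,
            "icm_ratio": icm / size,
            "icm_shape": shape,
            "kid": kid,
        }
    )


def render_embryo_masks(truth: SceneTruth) -> MaskFrame:
    """Rasterize a scene: a pixel belongs to a mask when its center lies
    inside the corresponding ellipse.

    The ICM raster is guaranteed to be a subset of the TE raster (the ICM
    ellipse must lie inside the TE ellipse).
    """
    if not ellipse_inside_image(truth.te_ellipse, truth.image_width, truth.image_height):
        raise ValueError("TE ellipse exceeds the image bounds")
    if not ellipse_inside_ellipse(truth.icm_ellipse, truth.te_ellipse, tol=1e-9):
        raise ValueError("ICM ellipse must lie entirely inside the TE ellipse")

    cols = np.arange(truth.image_width, dtype=float)
    rows = np.arange(truth.image_height, dtype=float)
    x, y = np.meshgrid(cols, rows)
    te = points_in_ellipse(truth.te_ellipse, x, y)
    icm = points_in_ellipse(truth.icm_ellipse, x, y) & te
    return MaskFrame(te_mask=te, icm_mask=icm, timestamp=truth.timestamp, scale=truth.scale)


def perturb_mask(
    mask: np.ndarray, mode: str, magnitude: int, seed: int = 0
) -> np.ndarray:
    """Degrade a binary mask to emulate an imperfect model prediction.

    ``translate`` shifts by ``magnitude`` pixels along a random axis
    direction (zero fill); ``dilate``/``erode`` apply a disk of radius
    ``magnitude``.  Magnitude 0 returns an unchanged copy.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot perturb an empty mask")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0:
        return mask.copy()

    if mode == "translate":
        rng = np.random.default_rng(seed)
        dy, dx = [(0, 1), (0, -1), (1, 0), (-1, 0)][rng.integers(4)]
        out = np.zeros_like(mask)
        m = magnitude
        src = mask[
            max(0, -dy * m) : mask.shape[0] - max(0, dy * m),
            max(0, -dx * m) : mask.shape[1] - max(0, dx * m),
        ]
        out[
            max(0, dy * m) : mask.shape[0] - max(0, -dy * m),
            max(0, dx * m) : mask.shape[1] - max(0, -dx * m),
        ] = src
    elif mode == "dilate":
        out = dilation(mask, disk(magnitude))
    elif mode == "erode":
        out = erosion(mask, disk(magnitude))
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")

    if not out.any():
        raise ValueError(f"perturbation {mode!r} at magnitude {magnitude} emptied the mask")
    return out


def sample_scene(
    rng: np.random.Generator,
    blastocyst_size_um: float,
    icm_size_um: float,
    icm_shape: float,
    *,
    scale: float = 1.0,
    timestamp: float = DEFAULT_MEASUREMENT_OFFSET_H,
    te_aspect_max: float = 1.15,
    margin_px: int = 8,
) -> SceneTruth:
    """Draw a scene whose rendered masks measure back to the given targets.

    The TE ellipse is mildly eccentric (aspect drawn uniformly on
    [1, ``te_aspect_max``]) at a random orientation, sized so the average of
    its axis-aligned bounding-box width and height equals
    ``blastocyst_size_um``.  The ICM ellipse has long diameter
    ``icm_size_um`` and elongation ``icm_shape``, placed at a random offset
    inside the TE (falling back to a concentric, co-aligned placement when a
    random offset cannot satisfy containment).
    """
    if icm_shape < 1.0:
        raise ValueError("icm_shape must be >= 1")

    size_px = blastocyst_size_um / scale
    aspect = float(rng.uniform(1.0, te_aspect_max))
    theta = float(rng.uniform(0.0, 180.0))
    # Scale a unit-major ellipse so the mean of its bbox dimensions hits size_px.
    unit = EllipseParams(0.0, 0.0, 1.0, 1.0 / aspect, theta)
    uw, uh = ellipse_bbox_dims(unit)
    te_major = size_px * 2.0 / (uw + uh)
    te_minor = te_major / aspect

    icm_major = icm_size_um / scale
    icm_minor = icm_major / icm_shape
    if icm_major > te_major or icm_minor > te_minor:
        raise ValueError(
            "ICM does not fit inside the TE ellipse for the requested sizes"
        )

    bbox_w, bbox_h = ellipse_bbox_dims(EllipseParams(0.0, 0.0, te_major, te_minor, theta))
    image_width = int(np.ceil(bbox_w)) + 2 * margin_px
    image_height = int(np.ceil(bbox_h)) + 2 * margin_px
    cx, cy = (image_width - 1) / 2.0, (image_height - 1) / 2.0
    te = EllipseParams(cx, cy, te_major, te_minor, theta)

    slack = max(0.0, (te_minor - icm_major) / 4.0)
    icm: EllipseParams | None = None
    for _ in range(20):
        cand = EllipseParams(
            cx + rng.uniform(-slack, slack),
            cy + rng.uniform(-slack, slack),
            icm_major,
            icm_minor,
            float(rng.uniform(0.0, 180.0)),
        )
        if ellipse_inside_ellipse(cand, te):
            icm = cand
            break
    if icm is None:
        # Concentric, co-aligned placement is contained whenever both
        # diameters fit (checked above).
        icm = EllipseParams(cx, cy, icm_major, icm_minor, theta)

    return SceneTruth(
        te_ellipse=te,
        icm_ellipse=icm,
        scale=scale,
        image_width=image_width,
        image_height=image_height,
        timestamp=timestamp,
    )
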