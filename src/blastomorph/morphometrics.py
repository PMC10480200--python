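"""Automated blastocyst morphometry from binary segmentation masks.

Four measurements are taken per embryo at the expanded-blastocyst frame
(the cohort-mean interval tEB - tPNf, 85.98 h after pronuclear fading):

* **blastocyst size** — the mean of the width and height of the tight
  axis-aligned bounding box around the trophectoderm mask (the outer TE
  contour, zona pellucida excluded), converted to micrometres;
* **ICM size** — the long diameter of the ellipse fitted to the ICM mask
  boundary in the direct algebraic least-squares sense;
* **ICM-to-blastocyst size ratio** — ICM size over blastocyst size;
* **ICM shape** — fitted-ellipse long over short diameter (1 = round).

Masks are the input contract; no segmentation of raw micrographs happens
here.  Fragmented masks are reduced to their largest connected component
(segmentation noise must not inflate bounding boxes); a warning is logged
when a competitor component is comparable in size.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import EllipseModel, label

from .datatypes import EllipseParams, MaskFrame, MorphometricResult

__all__ = [
    "blastocyst_size",
    "extract_icm_boundary",
    "fit_ellipse_lsq",
    "icm_measurements",
    "icm_ratio",
    "select_measurement_frame",
    "measure_frame",
    "DEFAULT_MEASUREMENT_OFFSET_H",
]

logger = logging.getLogger(__name__)

#: Mean time from pronuclear fading to blastocyst expansion, hours.
DEFAULT_MEASUREMENT_OFFSET_H = 85.98

#: A secondary connected component at least this fraction of the largest
#: one triggers a "comparable components" warning.
_COMPARABLE_COMPONENT_FRACTION = 0.5


def _resolve_scale(scale: float | None) -> float:
    if scale is None:
        warnings.warn(
            "no um/pixel scale provided; defaulting to 1.0 (pixel units)",
            UserWarning,
            stacklevel=3,
        )
        return 1.0
    if not (scale > 0):
        raise ValueError("scale must be positive (um per pixel)")
    return float(scale)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Boolean raster of the largest 8-connected foreground component."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    labels, n = label(mask, connectivity=2, return_num=True)
    if n == 1:
        return mask
    counts = np.bincount(labels.ravel())[1:]
    order = np.argsort(counts)[::-1]
    if counts[order[1]] >= _COMPARABLE_COMPONENT_FRACTION * counts[order[0]]:
        logger.warning(
            "mask has %d comparable connected components (%d vs %d px); keeping the largest",
            n,
            counts[order[0]],
            counts[order[1]],
        )
    return labels == order[0] + 1


def blastocyst_size(te_mask: np.ndarray, scale: float | None = None) -> float:
    """Blastocyst size in micrometres from the TE mask.

    The tight axis-aligned bounding box around the largest connected
    component is found and the mean of its width and height (inclusive
    pixel extents, ``max - min + 1``) is scaled to micrometres.
    """
    scale = _resolve_scale(scale)
    comp = _largest_component(te_mask)
    rows, cols = np.nonzero(comp)
    width = cols.max() - cols.min() + 1
    height = rows.max() - rows.min() + 1
    return scale * (width + height) / 2.0


def extract_icm_boundary(icm_mask: np.ndarray) -> np.ndarray:
    """Outer boundary pixels of the largest ICM component as (x, y) = (col, row).

    Interior holes are filled first so only the outer contour is returned.
    Points are ordered row-major (deterministic).  Fewer than 5 boundary
    points leave the ellipse underdetermined and raise ``ValueError``.
    """
    comp = _largest_component(icm_mask)
    filled = ndimage.binary_fill_holes(comp)
    boundary = filled & ~ndimage.binary_erosion(filled)
    rows, cols = np.nonzero(boundary)
    if rows.size < 5:
        raise ValueError(
            f"component has only {rows.size} boundary pixels; ellipse fit needs >= 5"
        )
    return np.column_stack([cols, rows]).astype(float)


def fit_ellipse_lsq(points: np.ndarray) -> EllipseParams:
    """Direct algebraic least-squares ellipse fit to a point set.

    Fits the conic constrained to be an ellipse (stability-improved direct
    least squares, as implemented by scikit-image's ``EllipseModel``) and
    converts to geometric parameters with ``major >= minor`` and the angle
    normalized to [0, 180).  Raises ``ValueError`` for fewer than 5 points
    or a degenerate (e.g. collinear) configuration.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y) coordinates")
    if pts.shape[0] < 5:
        raise ValueError("ellipse fit needs at least 5 points")

    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("degenerate point configuration: no ellipse fits")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])) or min(a, b) <= 1e-9:
        raise ValueError("degenerate point configuration: no ellipse fits")
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    return EllipseParams(
        center_x=float(xc),
        center_y=float(yc),
        major_diameter=2.0 * float(a),
        minor_diameter=2.0 * float(b),
        angle=float(np.rad2deg(theta)) % 180.0,
    )


def icm_measurements(
    icm_mask: np.ndarray, scale: float | None = None
) -> tuple[float, float]:
    """(ICM size in um, ICM shape) from the fitted boundary ellipse.

    ICM size is the long diameter of the least-squares ellipse; shape is the
    long over short diameter (>= 1 by construction).
    """
    scale = _resolve_scale(scale)
    ellipse = fit_ellipse_lsq(extract_icm_boundary(icm_mask))
    return scale * ellipse.major_diameter, ellipse.aspect


def icm_ratio(icm_size: float, blastocyst_size: float) -> float:
    """ICM-to-blastocyst size ratio (exact quotient)."""
    if not (blastocyst_size > 0):
        raise ValueError("blastocyst_size must be positive")
    return icm_size / blastocyst_size


def select_measurement_frame(
    frames: Sequence[MaskFrame],
    target_offset: float = DEFAULT_MEASUREMENT_OFFSET_H,
) -> MaskFrame:
    """Frame whose timestamp (hours post-tPNf) is nearest the target offset.

    Expects a time-sorted sequence; exact ties go to the earlier frame
    (pre-expansion frames are less likely to sit in a collapse).
    """
    if len(frames) == 0:
        raise ValueError("no frames to select from")
    best = frames[0]
    best_gap = abs(best.timestamp - target_offset)
    for frame in frames[1:]:
        gap = abs(frame.timestamp - target_offset)
        if gap < best_gap:
            best, best_gap = frame, gap
    return best


def measure_frame(frame: MaskFrame) -> MorphometricResult:
    """All four morphometrics for one frame, using its own um/pixel scale."""
    size = blastocyst_size(frame.te_mask, frame.scale)
    icm_size, icm_shape = icm_measurements(frame.icm_mask, frame.scale)
    return MorphometricResult(
        blastocyst_size=size,
        icm_size=icm_size,
        icm_ratio=icm_ratio(icm_size, size),
        icm_shape=icm_shape,
        measurement_time=frame.timestamp,
    )
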