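"""Analytic ellipse geometry used by the renderer and for test oracles."""

from __future__ import annotations

import numpy as np

from .datatypes import EllipseParams

__all__ = [
    "ellipse_bbox_dims",
    "points_in_ellipse",
    "ellipse_boundary_points",
    "ellipse_inside_ellipse",
    "ellipse_inside_image",
]


def ellipse_bbox_dims(ellipse: EllipseParams) -> tuple[float, float]:
    """Axis-aligned bounding-box (width, height) of an ellipse, continuous.

    For semi-axes a >= b at orientation theta the tight axis-aligned box has
    width 2*sqrt(a^2 cos^2(theta) + b^2 sin^2(theta)) and height
    2*sqrt(a^2 sin^2(theta) + b^2 cos^2(theta)).
    """
    a, b = ellipse.semi_major, ellipse.semi_minor
    t = np.deg2rad(ellipse.angle)
    width = 2.0 * np.hypot(a * np.cos(t), b * np.sin(t))
    height = 2.0 * np.hypot(a * np.sin(t), b * np.cos(t))
    return float(width), float(height)


def points_in_ellipse(
    ellipse: EllipseParams, x: np.ndarray, y: np.ndarray, *, tol: float = 0.0
) -> np.ndarray:
    """Boolean array: which (x, y) points lie inside (or on) the ellipse."""
    t = np.deg2rad(ellipse.angle)
    dx = np.asarray(x, dtype=float) - ellipse.center_x
    dy = np.asarray(y, dtype=float) - ellipse.center_y
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    return (u / ellipse.semi_major) ** 2 + (v / ellipse.semi_minor) ** 2 <= 1.0 + tol


def ellipse_boundary_points(ellipse: EllipseParams, n: int = 256) -> np.ndarray:
    """(n, 2) array of (x, y) points sampled uniformly in parameter angle."""
    phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    t = np.deg2rad(ellipse.angle)
    a, b = ellipse.semi_major, ellipse.semi_minor
    x = ellipse.center_x + a * np.cos(phi) * np.cos(t) - b * np.sin(phi) * np.sin(t)
    y = ellipse.center_y + a * np.cos(phi) * np.sin(t) + b * np.sin(phi) * np.cos(t)
    return np.column_stack([x, y])


def ellipse_inside_ellipse(
    inner: EllipseParams, outer: EllipseParams, *, n: int = 360, tol: float = 1e-9
) -> bool:
    """True when the inner ellipse lies entirely inside the outer one.

    Checked by testing a dense sample of the inner boundary; exact up to the
    sampling density, which suffices for the smooth shapes generated here.
    """
    pts = ellipse_boundary_points(inner, n=n)
    return bool(np.all(points_in_ellipse(outer, pts[:, 0], pts[:, 1], tol=tol)))


def ellipse_inside_image(ellipse: EllipseParams, width: int, height: int) -> bool:
    """True when the ellipse's continuous bounding box fits in the image."""
    w, h = ellipse_bbox_dims(ellipse)
    return (
        ellipse.center_x - w / 2.0 >= 0.0
        and ellipse.center_x + w / 2.0 <= width - 1
        and ellipse.center_y - h / 2.0 >= 0.0
        and ellipse.center_y + h / 2.0 <= height - 1
    )
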