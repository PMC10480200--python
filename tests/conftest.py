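"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from blastomorph.datatypes import EllipseParams, SceneTruth
from blastomorph.synthetic import render_embryo_masks


def ellipse_points(
    cx: float, cy: float, major: float, minor: float, angle_deg: float, n: int
) -> np.ndarray:
    """Exact points on an ellipse, independent of the package's geometry code."""
    phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    t = np.deg2rad(angle_deg)
    a, b = major / 2.0, minor / 2.0
    x = cx + a * np.cos(phi) * np.cos(t) - b * np.sin(phi) * np.sin(t)
    y = cy + a * np.cos(phi) * np.sin(t) + b * np.sin(phi) * np.cos(t)
    return np.column_stack([x, y])


def brute_force_disk(radius: float, size: int = 0, center: float | None = None):
    """Rasterized disk by direct pixel-center membership (oracle path)."""
    if size == 0:
        size = int(2 * radius) + 21
    if center is None:
        center = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - center) ** 2 + (yy - center) ** 2 <= radius**2


def auc_pair_count(scores, labels) -> float:
    """Exhaustive Mann-Whitney AUC: concordant pairs plus half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


@pytest.fixture
def rendered_circle_scene():
    """TE circle (diameter 100 px) with an oblique ICM ellipse (60 x 40 px)."""
    te = EllipseParams(100.0, 100.0, 100.0, 100.0)
    icm = EllipseParams(100.0, 100.0, 60.0, 40.0, 30.0)
    truth = SceneTruth(te, icm, scale=1.0, image_width=200, image_height=200)
    return truth, render_embryo_masks(truth)
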