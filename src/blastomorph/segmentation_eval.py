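"""Segmentation agreement metrics: intersection-over-union and
threshold-exceedance fractions.

IOU is the validation metric for the upstream TE/ICM segmentation: the
fraction of frames whose predicted mask overlaps the expert-annotated mask
by more than a threshold (0.5 and 0.75 by default) summarizes model
quality.  Exceedance is strict (``> t``).  Because "overlap in more than
50% of the pixels" can also be read as pixel recall, :func:`pixel_recall`
is provided alongside and both are reported by the pipeline.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .datatypes import IOUReport

__all__ = ["iou", "pixel_recall", "threshold_fractions"]


def _as_bool_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask dimensions differ: {a.shape} vs {b.shape}")
    return a, b


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two binary masks.

    Two empty masks agree on absence and score 1.0; empty vs nonempty is 0.
    """
    a, b = _as_bool_pair(mask_a, mask_b)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def pixel_recall(pred: np.ndarray, ref: np.ndarray) -> float:
    """Fraction of reference pixels covered by the prediction."""
    p, r = _as_bool_pair(pred, ref)
    n_ref = np.count_nonzero(r)
    if n_ref == 0:
        return 1.0
    return np.count_nonzero(p & r) / n_ref


def threshold_fractions(
    ious: Sequence[float], thresholds: Iterable[float] = (0.5, 0.75)
) -> IOUReport:
    """Fraction of frames with IOU strictly above each threshold."""
    values = np.asarray(list(ious), dtype=float)
    if values.size == 0:
        raise ValueError("no IOU values given")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("IOU values must lie in [0, 1]")
    fractions = {float(t): float(np.mean(values > t)) for t in thresholds}
    return IOUReport(
        per_frame_iou=[float(v) for v in values],
        frac_above_50=float(np.mean(values > 0.5)),
        frac_above_75=float(np.mean(values > 0.75)),
        n_frames=int(values.size),
        fractions=fractions,
    )
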