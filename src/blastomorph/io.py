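"""Reading and writing the pipeline's on-disk formats.

Masks are single-channel 8-bit PNGs (0 = background, 255 = foreground; any
nonzero value counts as foreground on read).  Scene truths travel as one
JSON sidecar per frame; cohorts and morphometric tables are CSV with the
canonical column names so outputs merge by ``embryo_id``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .datatypes import EllipseParams, SceneTruth

__all__ = [
    "write_mask_png",
    "read_mask_png",
    "write_scene_sidecar",
    "read_scene_sidecar",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_json",
]


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask_png(path: str | Path) -> np.ndarray:
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:  # tolerate RGB(A) exports
        img = img[..., :3].max(axis=-1)
    return img > 0


def write_scene_sidecar(path: str | Path, truth: SceneTruth) -> None:
    payload = {
        "te_ellipse": dataclasses.asdict(truth.te_ellipse),
        "icm_ellipse": dataclasses.asdict(truth.icm_ellipse),
        "scale": truth.scale,
        "image_width": truth.image_width,
        "image_height": truth.image_height,
        "timestamp": truth.timestamp,
    }
    write_json(path, payload)


def read_scene_sidecar(path: str | Path) -> SceneTruth:
    payload = json.loads(Path(path).read_text())
    return SceneTruth(
        te_ellipse=EllipseParams(**payload["te_ellipse"]),
        icm_ellipse=EllipseParams(**payload["icm_ellipse"]),
        scale=payload["scale"],
        image_width=payload["image_width"],
        image_height=payload["image_height"],
        timestamp=payload["timestamp"],
    )


def write_cohort_csv(path: str | Path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(Path(path), index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_json(path: str | Path, payload: dict) -> None:
    """Serialize at full precision with stable key order (reproducible bytes)."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
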