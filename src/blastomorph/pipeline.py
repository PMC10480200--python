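"""End-to-end orchestration: simulate -> render -> measure -> evaluate -> analyze.

Stages are isolated — each consumes and produces only its declared files —
and a single master seed is fanned out into per-stage child seeds via
``numpy.random.SeedSequence`` so every stage is independently reproducible.
Each run writes a manifest echoing the resolved configuration, the seeds,
and which stages completed (also on partial failure).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometrics, segmentation_eval
from .association import analysis_report
from .io import (
    read_cohort_csv,
    read_mask_png,
    read_scene_sidecar,
    write_cohort_csv,
    write_json,
    write_mask_png,
    write_scene_sidecar,
)
from .synthetic import (
    DEFAULT_MEASUREMENT_OFFSET_H,
    CohortGenConfig,
    generate_cohort,
    perturb_mask,
    render_embryo_masks,
    sample_scene,
)

__all__ = ["RunConfig", "run_simulate", "run_measure", "run_evaluate", "run_analyze", "run_full"]

logger = logging.getLogger(__name__)

_STAGE_NAMES = ("simulate", "measure", "evaluate", "analyze")


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run."""

    out_dir: Path
    seed: int = 0
    n_embryos: int = 500
    n_scenes: int | None = None  # embryos to render; None = all
    scale_um_per_px: float = 1.0
    perturb_mode: str = "translate"
    perturb_magnitude: int = 3
    target_offset_h: float = DEFAULT_MEASUREMENT_OFFSET_H
    cohort: dict = field(default_factory=dict)  # CohortGenConfig overrides

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        import json

        payload = json.loads(Path(path).read_text())
        payload.update(overrides)
        payload["out_dir"] = Path(payload["out_dir"])
        return cls(**payload)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d


def _child_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic per-stage seeds below 2**31 from one master seed."""
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def run_simulate(config: RunConfig) -> dict:
    """Generate the cohort, render mask scenes, and write perturbed predictions."""
    out = Path(config.out_dir)
    masks_dir = out / "masks"
    pred_dir = out / "masks_pred"
    masks_dir.mkdir(parents=True, exist_ok=True)
    pred_dir.mkdir(parents=True, exist_ok=True)
    cohort_seed, scene_seed, perturb_seed, _ = _child_seeds(config.seed)

    gen = CohortGenConfig(
        n_embryos=config.n_embryos, seed=cohort_seed, **config.cohort
    )
    cohort = generate_cohort(gen)
    write_cohort_csv(out / "cohort.csv", cohort)

    rng = np.random.default_rng(scene_seed)
    n_scenes = config.n_scenes if config.n_scenes is not None else len(cohort)
    rendered = 0
    for _, row in cohort.head(n_scenes).iterrows():
        truth = sample_scene(
            rng,
            blastocyst_size_um=row["blastocyst_size_um"],
            icm_size_um=row["icm_size_um"],
            icm_shape=row["icm_shape"],
            scale=config.scale_um_per_px,
            timestamp=config.target_offset_h,
        )
        frame = render_embryo_masks(truth)
        stem = row["embryo_id"]
        write_mask_png(masks_dir / f"{stem}_te.png", frame.te_mask)
        write_mask_png(masks_dir / f"{stem}_icm.png", frame.icm_mask)
        write_scene_sidecar(masks_dir / f"{stem}.json", truth)
        for kind, mask in (("te", frame.te_mask), ("icm", frame.icm_mask)):
            pred = perturb_mask(
                mask, config.perturb_mode, config.perturb_magnitude,
                seed=(perturb_seed + rendered) % (2**31),
            )
            write_mask_png(pred_dir / f"{stem}_{kind}.png", pred)
        rendered += 1
    logger.info("simulate: %d cohort rows, %d scenes rendered", len(cohort), rendered)
    return {"n_embryos": len(cohort), "n_scenes": rendered}


def run_measure(config: RunConfig) -> dict:
    """Measure every rendered embryo; write the morphometric CSV."""
    out = Path(config.out_dir)
    masks_dir = out / "masks"
    rows = []
    for sidecar in sorted(masks_dir.glob("E*.json")):
        stem = sidecar.stem
        truth = read_scene_sidecar(sidecar)
        from .datatypes import MaskFrame

        frame = MaskFrame(
            te_mask=read_mask_png(masks_dir / f"{stem}_te.png"),
            icm_mask=read_mask_png(masks_dir / f"{stem}_icm.png"),
            timestamp=truth.timestamp,
            scale=truth.scale,
        )
        selected = morphometrics.select_measurement_frame([frame], config.target_offset_h)
        result = morphometrics.measure_frame(selected)
        rows.append(
            {
                "embryo_id": stem,
                "blastocyst_size_um": result.blastocyst_size,
                "icm_size_um": result.icm_size,
                "icm_ratio": result.icm_ratio,
                "icm_shape": result.icm_shape,
                "measurement_time_h": result.measurement_time,
            }
        )
    if not rows:
        raise FileNotFoundError(f"no rendered scenes found under {masks_dir}")
    table = pd.DataFrame(rows)
    table.to_csv(out / "morphometrics.csv", index=False)
    logger.info("measure: %d embryos measured", len(table))
    return {"n_measured": len(table)}


def run_evaluate(config: RunConfig) -> dict:
    """IOU (and pixel recall) between rendered and perturbed masks, per tissue."""
    out = Path(config.out_dir)
    masks_dir = out / "masks"
    pred_dir = out / "masks_pred"
    report: dict = {}
    for kind in ("te", "icm"):
        ious, recalls = [], []
        for ref_path in sorted(masks_dir.glob(f"E*_{kind}.png")):
            pred_path = pred_dir / ref_path.name
            if not pred_path.exists():
                continue
            ref = read_mask_png(ref_path)
            pred = read_mask_png(pred_path)
            ious.append(segmentation_eval.iou(pred, ref))
            recalls.append(segmentation_eval.pixel_recall(pred, ref))
        if not ious:
            raise FileNotFoundError(f"no paired {kind} masks under {pred_dir}")
        frac = segmentation_eval.threshold_fractions(ious)
        report[kind] = {
            "n_frames": frac.n_frames,
            "mean_iou": float(np.mean(ious)),
            "frac_iou_above_50": frac.frac_above_50,
            "frac_iou_above_75": frac.frac_above_75,
            "mean_pixel_recall": float(np.mean(recalls)),
            "frac_recall_above_50": float(np.mean(np.asarray(recalls) > 0.5)),
        }
    write_json(out / "iou_report.json", report)
    return report


def run_analyze(config: RunConfig, cohort_csv: str | Path | None = None) -> dict:
    """Association analysis on a cohort CSV (defaults to the run's own).

    In a full run the measured morphometrics replace the generator's sampled
    values for every rendered embryo before analysis, so the statistics see
    the pipeline's own measurements end to end.
    """
    out = Path(config.out_dir)
    if cohort_csv is not None:
        cohort = read_cohort_csv(cohort_csv)
    else:
        cohort = read_cohort_csv(out / "cohort.csv")
        measured_path = out / "morphometrics.csv"
        if measured_path.exists():
            measured = pd.read_csv(measured_path)
            merged = cohort.merge(
                measured.drop(columns=["measurement_time_h"]),
                on="embryo_id",
                how="left",
                suffixes=("_gen", ""),
            )
            for col in ("blastocyst_size_um", "icm_size_um", "icm_ratio", "icm_shape"):
                merged[col] = merged[col].fillna(merged[f"{col}_gen"])
                merged = merged.drop(columns=[f"{col}_gen"])
            write_cohort_csv(out / "cohort_measured.csv", merged)
            # Re-read so a later analyze-only run on the written CSV sees
            # the identical (round-tripped) values and report.
            cohort = read_cohort_csv(out / "cohort_measured.csv")

    report = analysis_report(cohort)
    write_json(out / "report.json", report)
    return report


def run_full(config: RunConfig) -> dict:
    """Run every stage; write a manifest recording completed stages."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_manifest(),
        "child_seeds": _child_seeds(config.seed),
        "stages_completed": [],
    }
    stages = {
        "simulate": lambda: run_simulate(config),
        "measure": lambda: run_measure(config),
        "evaluate": lambda: run_evaluate(config),
        "analyze": lambda: run_analyze(config),
    }
    try:
        for name, stage in stages.items():
            stage()
            manifest["stages_completed"].append(name)
    finally:
        write_json(out / "manifest.json", manifest)
    return manifest
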