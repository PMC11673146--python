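"""End-to-end orchestration: cohort in, full report set out.

Stage order follows the analysis design: label-distribution summary,
keypoint screening, phase segmentation, pelvis feature table, per-fold
penalized selection with frequency analysis and VIF diagnostics,
four-family model comparison, and the final single-feature linear model.
Every run writes its reports plus a log naming the config hash and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import build_pelvis_features, screen_keypoints
from .io import KeypointRegistry, read_cohort
from .modeling import (
    SelectionConfig,
    compare_models,
    fit_final_single_feature,
    plot_predictions,
    run_selection,
)
from .preprocessing import DEFAULT_WINDOW, moving_average
from .segmentation import SegmentationConfig, segment_phases
from .sppb import SppbInput, score_sppb, summarize_label

logger = logging.getLogger(__name__)

REPORT_FILES = (
    "label_summary.json",
    "screening.csv",
    "segmentation.csv",
    "features.csv",
    "selection.csv",
    "frequency.csv",
    "model_comparison.csv",
    "final_model.json",
)


@dataclass
class PipelineConfig:
    cohort_dir: str = "cohort"
    output_dir: str = "run"
    window: int = DEFAULT_WINDOW
    top_k: int = 10
    n_folds: int = 5
    max_features: int = 3
    seed: int = 0
    segmentation_delta: float = 0.15
    segmentation_min_amplitude: float = 0.15
    min_phase_frames: int = 6
    ceiling_threshold: float = 0.4
    keypoints: tuple[str, ...] = field(
        default_factory=lambda: KeypointRegistry().names
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "keypoints" in raw:
            raw["keypoints"] = tuple(raw["keypoints"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["keypoints"] = list(out["keypoints"])
        return out

    @property
    def config_hash(self) -> str:
        """Hash of the analysis settings (the output path does not alter
        what is computed and is excluded)."""
        payload = {k: v for k, v in self.as_dict().items() if k != "output_dir"}
        canonical = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages on the cohort under ``config.cohort_dir``.

    Returns the output directory.  Any stage error aborts with the stage
    name (and subject id where applicable); reports written so far are
    retained for debugging.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = KeypointRegistry(config.keypoints)
    sel_config = SelectionConfig(
        n_folds=config.n_folds, max_features=config.max_features, seed=config.seed
    )
    seg_config = SegmentationConfig(
        delta=config.segmentation_delta,
        min_amplitude=config.segmentation_min_amplitude,
        min_phase_frames=config.min_phase_frames,
    )
    run_log: dict = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "pvv_version": __version__,
        "stages": [],
    }

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            run_log["stages"].append({"stage": name, "error": str(exc)})
            (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        dt = time.perf_counter() - t0
        logger.info("stage %-16s done in %.2f s", name, dt)
        run_log["stages"].append({"stage": name, "seconds": round(dt, 3)})
        return result

    cohort, labels = _stage(
        "load_cohort", lambda: read_cohort(config.cohort_dir, registry)
    )
    run_log["n_subjects"] = len(cohort)
    tug = labels["tug_s"].to_numpy(dtype=float)

    def label_summary():
        summary = {"tug": dataclasses.asdict(summarize_label(tug))}
        sppb_cols = {"side_by_side_s", "semi_tandem_s", "tandem_s", "walk4m_s", "sts5_s"}
        if sppb_cols.issubset(labels.columns):
            totals = [
                score_sppb(
                    SppbInput(
                        side_by_side_hold=row["side_by_side_s"],
                        semi_tandem_hold=row["semi_tandem_s"],
                        tandem_hold=row["tandem_s"],
                        walk4m_time=row["walk4m_s"],
                        sts5_time=row["sts5_s"],
                    )
                ).total
                for _, row in labels.iterrows()
            ]
            summary["sppb_total"] = dataclasses.asdict(
                summarize_label(
                    totals, max_possible=12,
                    ceiling_threshold=config.ceiling_threshold,
                )
            )
            chosen = "tug" if summary["tug"]["imbalanced"] is False else "review"
            summary["recommended_label"] = chosen
        (out / "label_summary.json").write_text(json.dumps(summary, indent=1))
        return summary

    _stage("label_summary", label_summary)

    screening = _stage(
        "screening",
        lambda: screen_keypoints(cohort, tug, registry, config.window, config.top_k),
    )
    screening.to_csv(out / "screening.csv", index=False)

    def segment_all():
        segs, rows = {}, []
        for rec in cohort:
            pelvis_z = rec.get_axes("Pelvis", "pos")[2]
            smoothed = moving_average(pelvis_z, config.window)
            try:
                seg = segment_phases(smoothed, rec.sampling_rate, seg_config)
            except Exception as exc:
                raise RuntimeError(f"subject '{rec.subject_id}': {exc}") from exc
            segs[rec.subject_id] = seg
            b1, b2, b3 = seg.boundaries
            rows.append(
                {"subject_id": rec.subject_id, "b1": b1, "b2": b2, "b3": b3,
                 **{f"{k}_s": v for k, v in seg.durations_s(rec.sampling_rate).items()}}
            )
        pd.DataFrame(rows).to_csv(out / "segmentation.csv", index=False)
        return segs

    segmentations = _stage("segmentation", segment_all)

    table = _stage(
        "features",
        lambda: build_pelvis_features(
            cohort, segmentations, tug, config.window
        ).impute_missing(),
    )
    table.to_csv(out / "features.csv")

    selection = _stage("selection", lambda: run_selection(table, sel_config))
    sel_rows = []
    for fs in selection.per_fold:
        for name, coef in fs.coefficients.items():
            sel_rows.append(
                {"fold": fs.fold, "alpha": fs.alpha, "feature": name,
                 "coefficient": float(coef),
                 "vif": float(fs.vif[name]) if fs.vif is not None else np.nan}
            )
    pd.DataFrame(sel_rows).to_csv(out / "selection.csv", index=False)
    selection.frequency_frame().to_csv(out / "frequency.csv", index=False)

    comparison = _stage(
        "model_comparison", lambda: compare_models(table, selection, sel_config)
    )
    comparison.to_csv(out / "model_comparison.csv", index=False)

    result = _stage(
        "final_model",
        lambda: fit_final_single_feature(table, selection.final_feature, sel_config),
    )
    final = {
        "config_hash": config.config_hash,
        "final_feature": selection.final_feature,
        "per_fold": result.per_fold.to_dict(orient="records"),
        "mean_mae_s": result.mean_mae,
        "mean_pearson_r": result.mean_r,
        "pooled_mae_s": result.pooled_mae,
        "pooled_pearson_r": result.pooled_r,
    }
    (out / "final_model.json").write_text(json.dumps(final, indent=1))
    result.predictions.to_csv(out / "predictions.csv", index=False)
    plot_predictions(result, out / "predicted_vs_actual.png")

    (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
    return out
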