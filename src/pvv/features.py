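"""Keypoint screening and the 120-feature pelvis table.

Screening correlates whole-trial horizontal-plane velocity statistics of
every keypoint with the TUG label to pick the body location worth detailed
feature engineering.  The pelvis feature table then crosses
3 directions (z, xy, xyz) x 4 statistics (Max, Min, Mean, SD) x
2 signals (Vel, Acc) x 5 phases (the four movement phases plus the whole
trial) = 120 named columns.  The pelvis velocity variability statistic
(PVV) is the column ``xyz_SD_Vel_Throughout``: the standard deviation of
the 3-D pelvis speed over the whole trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import KeypointRegistry, TrialRecording
from .preprocessing import ChannelMissingError, DEFAULT_WINDOW, project_speed
from .segmentation import PhaseSegmentation

logger = logging.getLogger(__name__)

DIRECTIONS = ("z", "xy", "xyz")
STATS = ("Max", "Min", "Mean", "SD")
FEATURE_SIGNALS = ("Vel", "Acc")
PHASES = ("Standing", "Sitting_down", "Sitting", "Standing_up", "Throughout")

#: The PVV column: SD of the 3-D pelvis speed over the whole trial.
PVV_FEATURE = "xyz_SD_Vel_Throughout"


def feature_names() -> list[str]:
    """The full 120-name scheme, ``<direction>_<Stat>_<Signal>_<Phase>``."""
    return [
        f"{d}_{stat}_{sig}_{phase}"
        for d in DIRECTIONS
        for stat in STATS
        for sig in FEATURE_SIGNALS
        for phase in PHASES
    ]


@dataclass
class FeatureTable:
    """Subjects x named-features matrix with the TUG label vector."""

    values: pd.DataFrame  # index: subject_id, columns: feature names
    label: pd.Series      # TUG seconds, aligned to values.index

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.label.index):
            raise ValueError("feature matrix and label must share the subject index")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    def impute_missing(self) -> "FeatureTable":
        """Median-impute missing phase features (logged), column-wise."""
        missing = self.values.isna()
        if missing.any().any():
            cols = list(self.values.columns[missing.any()])
            logger.info("imputing cohort median for %d feature columns: %s",
                        len(cols), cols[:8])
        return FeatureTable(self.values.fillna(self.values.median()), self.label)

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "subject_id", out.index)
        out["tug_s"] = self.label
        out.to_csv(path, index=False, float_format="%.17g")


def pearson_r(x, y) -> float:
    """Product-moment correlation; rejects degenerate inputs loudly.

    Zero variance in either series makes the correlation undefined and
    raises instead of silently returning 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 points")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt((xd**2).sum()))
    sy = float(np.sqrt((yd**2).sum()))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance: Pearson correlation is undefined")
    r = float((xd * yd).sum() / (sx * sy))
    return max(-1.0, min(1.0, r))


def coefficient_of_variation(series) -> float:
    """CoV = SD / mean (population SD); undefined for zero mean."""
    x = np.asarray(series, dtype=float)
    mean = float(x.mean())
    if mean == 0.0:
        raise ValueError("coefficient of variation is undefined for zero mean")
    return float(x.std()) / mean


def screen_keypoints(
    cohort: list[TrialRecording],
    labels,
    registry: KeypointRegistry | None = None,
    window: int = DEFAULT_WINDOW,
    top_k: int = 10,
) -> pd.DataFrame:
    """Rank keypoints by |Pearson r| of whole-trial xy-plane speed statistics.

    For every registered keypoint present in all recordings, the smoothed
    horizontal-plane velocity magnitude is reduced to per-subject Max, Min
    and Mean, each correlated with the label.  Returns the ``top_k`` rows of
    (keypoint, statistic, r, abs_r), ranked by abs_r descending with a
    deterministic tie-break (keypoint name, then statistic).  Keypoints
    missing from any recording are excluded with a warning.
    """
    labels = np.asarray(labels, dtype=float)
    if len(cohort) < 3:
        raise ValueError("screening needs at least 3 subjects")
    if len(labels) != len(cohort):
        raise ValueError("labels must align with the cohort")
    registry = registry or KeypointRegistry()

    rows = []
    for kp in registry:
        try:
            speeds = [
                project_speed(rec, kp, "Vel", "xy", window).values for rec in cohort
            ]
        except ChannelMissingError as exc:
            logger.warning("screening skips keypoint %s: %s", kp, exc)
            continue
        stats = {
            "Max": np.array([s.max() for s in speeds]),
            "Min": np.array([s.min() for s in speeds]),
            "Mean": np.array([s.mean() for s in speeds]),
        }
        for stat, vals in stats.items():
            r = pearson_r(vals, labels)
            rows.append(
                {"keypoint": kp, "statistic": stat, "r": r, "abs_r": abs(r)}
            )
    report = pd.DataFrame(rows)
    report = report.sort_values(
        ["abs_r", "keypoint", "statistic"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return report.head(top_k)


def _phase_slices(seg: PhaseSegmentation) -> dict[str, slice]:
    slices = {name: slice(*bounds) for name, bounds in seg.phases.items()}
    slices["Throughout"] = slice(0, seg.n_frames)
    return slices


def build_pelvis_features(
    cohort: list[TrialRecording],
    segmentations: dict[str, PhaseSegmentation],
    labels,
    window: int = DEFAULT_WINDOW,
    keypoint: str = "Pelvis",
) -> FeatureTable:
    """Build the 120-column pelvis feature table.

    For each subject, each of velocity and acceleration is projected onto
    z / xy / xyz, smoothed, restricted to each movement phase (plus the
    whole trial), and reduced to Max, Min, Mean and SD.  The SD uses the
    population denominator n.  Phases shorter than 2 frames yield missing
    values (flagged; impute before modelling).
    """
    labels = pd.Series(
        np.asarray(labels, dtype=float), index=[rec.subject_id for rec in cohort]
    )
    names = feature_names()
    data = {}
    for rec in cohort:
        seg = segmentations[rec.subject_id]
        if seg.n_frames != rec.n_frames:
            raise ValueError(
                f"segmentation for '{rec.subject_id}' covers {seg.n_frames} frames, "
                f"recording has {rec.n_frames}"
            )
        slices = _phase_slices(seg)
        row = {}
        for d in DIRECTIONS:
            for sig in FEATURE_SIGNALS:
                series = project_speed(rec, keypoint, sig, d, window).values
                for phase, sl in slices.items():
                    part = series[sl]
                    if len(part) < 2:
                        logger.warning(
                            "subject %s: phase %s shorter than 2 frames; "
                            "features set to missing", rec.subject_id, phase,
                        )
                        vals = dict.fromkeys(STATS, np.nan)
                    else:
                        vals = {
                            "Max": float(part.max()),
                            "Min": float(part.min()),
                            "Mean": float(part.mean()),
                            "SD": float(part.std()),  # population n
                        }
                    for stat in STATS:
                        row[f"{d}_{stat}_{sig}_{phase}"] = vals[stat]
        data[rec.subject_id] = row
    values = pd.DataFrame.from_dict(data, orient="index")[names]
    values.index.name = "subject_id"
    return FeatureTable(values=values, label=labels)
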