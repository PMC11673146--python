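"""Reading and writing multi-keypoint trial recordings as wide CSV files.

A trial is one subject's consultation-room movement sequence exported as
per-keypoint kinematic time series: position, velocity and acceleration in
x, y, z at a fixed frame rate.  One CSV holds one trial; columns are named
``<Keypoint>_<signal>_<axis>`` (e.g. ``Pelvis_vel_z``), plus a leading
``time_s`` column.  Units are metres, m/s and m/s^2; frames are 0-based with
frame 0 at t = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SIGNALS = ("pos", "vel", "acc")
AXES = ("x", "y", "z")

#: Default keypoint set: the 23 body segments of a full-body motion-capture
#: export (head/trunk/pelvis plus bilateral limb segments).  The pipeline
#: itself only requires that "Pelvis" be present.
DEFAULT_KEYPOINTS = (
    "Pelvis", "L5", "L3", "T12", "T8", "Neck", "Head",
    "RightShoulder", "RightUpperArm", "RightForearm", "RightHand",
    "LeftShoulder", "LeftUpperArm", "LeftForearm", "LeftHand",
    "RightUpperLeg", "RightLowerLeg", "RightFoot", "RightToe",
    "LeftUpperLeg", "LeftLowerLeg", "LeftFoot", "LeftToe",
)


class TrialParseError(ValueError):
    """A trial CSV does not conform to the documented layout."""


@dataclass(frozen=True)
class KeypointRegistry:
    """Ordered registry of keypoint labels; defines CSV column order."""

    names: tuple[str, ...] = DEFAULT_KEYPOINTS

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise ValueError("keypoint names must be unique")
        if "Pelvis" not in names:
            raise ValueError("registry must contain 'Pelvis'")

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class TrialRecording:
    """One subject's kinematic time series.

    ``channels`` maps ``(keypoint, signal, axis)`` to a 1-D float array; all
    present arrays share the same length ``n_frames``.
    """

    subject_id: str
    sampling_rate: float
    channels: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if self.channels:
            if len(lengths) != 1:
                raise ValueError(
                    f"channel series have inconsistent lengths: {sorted(lengths)}"
                )
            if min(lengths) < 2:
                raise ValueError("recordings need at least 2 frames")

    @property
    def n_frames(self) -> int:
        if not self.channels:
            return 0
        return len(next(iter(self.channels.values())))

    @property
    def keypoints(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for kp, _, _ in self.channels:
            seen.setdefault(kp)
        return tuple(seen)

    def has(self, keypoint: str, signal: str) -> bool:
        return all((keypoint, signal, ax) in self.channels for ax in AXES)

    def get_axes(self, keypoint: str, signal: str) -> np.ndarray:
        """Return the (3, n_frames) array of x, y, z series for a signal."""
        try:
            return np.stack(
                [self.channels[(keypoint, signal, ax)] for ax in AXES]
            )
        except KeyError as exc:
            raise KeyError(
                f"channel {keypoint}_{signal}_{exc.args[0][2]} is absent"
            ) from None


def _column_name(keypoint: str, signal: str, axis: str) -> str:
    return f"{keypoint}_{signal}_{axis}"


def _parse_column(name: str, registry: KeypointRegistry, path: Path) -> tuple[str, str, str]:
    parts = name.rsplit("_", 2)
    if len(parts) != 3:
        raise TrialParseError(
            f"{path}: column '{name}' is not of the form <Keypoint>_<signal>_<axis>"
        )
    keypoint, signal, axis = parts
    if keypoint not in registry:
        raise TrialParseError(
            f"{path}: column '{name}' references unregistered keypoint '{keypoint}'"
        )
    if signal not in SIGNALS:
        raise TrialParseError(
            f"{path}: column '{name}' has unknown signal '{signal}' "
            f"(expected one of {SIGNALS})"
        )
    if axis not in AXES:
        raise TrialParseError(
            f"{path}: column '{name}' has unknown axis '{axis}'"
        )
    return keypoint, signal, axis


def read_trial(
    path: str | Path,
    registry: KeypointRegistry | None = None,
    sampling_rate: float = 60.0,
) -> TrialRecording:
    """Read one trial CSV into a validated :class:`TrialRecording`.

    The sampling rate is taken from the ``time_s`` column when present
    (spacing of the first two rows), else from ``sampling_rate``.
    Missing signals are permitted; missing velocity is derived downstream by
    the preprocessing stage, not here.
    """
    registry = registry or KeypointRegistry()
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TrialParseError(f"{path}: malformed CSV ({exc})") from exc
    if frame.shape[0] < 2:
        raise TrialParseError(f"{path}: fewer than 2 data rows")

    channels: dict[tuple[str, str, str], np.ndarray] = {}
    for name in frame.columns:
        if name == "time_s":
            continue
        key = _parse_column(name, registry, path)
        col = pd.to_numeric(frame[name], errors="coerce")
        if col.isna().any():
            row = int(col.isna().idxmax())
            raise TrialParseError(
                f"{path}: non-numeric value in column '{name}', row {row}"
            )
        channels[key] = col.to_numpy(dtype=float)
    if not channels:
        raise TrialParseError(f"{path}: no keypoint channels found")

    if "time_s" in frame.columns:
        dt = float(frame["time_s"].iloc[1] - frame["time_s"].iloc[0])
        if dt <= 0:
            raise TrialParseError(f"{path}: non-increasing time_s column")
        sampling_rate = 1.0 / dt

    return TrialRecording(
        subject_id=path.stem, sampling_rate=sampling_rate, channels=channels
    )


def write_trial(recording: TrialRecording, path: str | Path) -> Path:
    """Write a trial CSV with deterministic column order.

    Column order is a pure function of the registry order implied by the
    recording's channels: registry keypoint order x signal (pos, vel, acc)
    x axis (x, y, z), preceded by ``time_s = frame / sampling_rate``.
    """
    if not recording.channels:
        raise ValueError("recording has no channels; nothing to write")
    path = Path(path)
    n = recording.n_frames

    ordered_keypoints = [
        kp for kp in DEFAULT_KEYPOINTS if any(k[0] == kp for k in recording.channels)
    ]
    # keypoints outside the default registry order go last, alphabetically
    extra = sorted({k[0] for k in recording.channels} - set(ordered_keypoints))
    data: dict[str, np.ndarray] = {
        "time_s": np.arange(n, dtype=float) / recording.sampling_rate
    }
    for kp in ordered_keypoints + extra:
        for sig in SIGNALS:
            for ax in AXES:
                key = (kp, sig, ax)
                if key in recording.channels:
                    data[_column_name(kp, sig, ax)] = recording.channels[key]

    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    return path


def write_labels(labels: pd.DataFrame, path: str | Path) -> Path:
    """Write the per-subject labels CSV (subject_id, tug_s, SPPB times)."""
    path = Path(path)
    labels.to_csv(path, index=False, float_format="%.17g")
    return path


def read_labels(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "subject_id" not in frame.columns or "tug_s" not in frame.columns:
        raise TrialParseError(f"{path}: labels CSV needs subject_id and tug_s columns")
    return frame


def read_cohort(
    directory: str | Path,
    registry: KeypointRegistry | None = None,
) -> tuple[list[TrialRecording], pd.DataFrame]:
    """Read every trial CSV under ``directory/trials`` plus the labels CSV.

    Trials are matched to label rows by subject_id; subjects missing from
    either side raise an error.
    """
    directory = Path(directory)
    labels = read_labels(directory / "labels.csv")
    trial_dir = directory / "trials"
    recordings = []
    for sid in labels["subject_id"]:
        trial_path = trial_dir / f"{sid}.csv"
        if not trial_path.exists():
            raise FileNotFoundError(f"no trial file for subject '{sid}': {trial_path}")
        recordings.append(read_trial(trial_path, registry))
    return recordings, labels
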