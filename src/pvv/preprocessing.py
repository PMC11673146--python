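"""Smoothing and direction-projected speed signals.

All downstream stages consume keypoint speed series in one of three
projections: the signed vertical component (``z``), the horizontal-plane
magnitude (``xy``), and the full 3-D magnitude (``xyz``).  Each axis is
smoothed with a centred moving average before magnitudes are taken;
smoothing a magnitude directly would bias it upward near zero crossings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import TrialRecording

PROJECTIONS = ("z", "xy", "xyz")
SPEED_SIGNALS = {"Vel": "vel", "Acc": "acc"}

#: Smoothing window used throughout: 5 frames = 5/60 s at 60 frames/s.
DEFAULT_WINDOW = 5


class ChannelMissingError(KeyError):
    """A required kinematic channel is absent and cannot be derived."""


@dataclass
class SpeedSeries:
    """A projected, smoothed speed (or acceleration-magnitude) series.

    Values are non-negative for the ``xy`` and ``xyz`` projections (they are
    magnitudes); the ``z`` projection retains its sign.
    """

    keypoint: str
    projection: str
    signal: str
    values: np.ndarray
    sampling_rate: float


def moving_average(series, window: int) -> np.ndarray:
    """Centred moving mean with shrinking windows at the edges.

    The output has the same length as the input; near the boundaries the
    window is truncated to the available samples so that phase boundaries
    stay frame-aligned.  ``window`` must be odd so the window is symmetric.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if len(x) < window:
        raise ValueError(f"series length {len(x)} is shorter than window {window}")
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones(len(x)), kernel, mode="same")
    return num / den


def derive_velocity(position: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Central finite differences of position (one-sided at the ends)."""
    return np.gradient(np.asarray(position, dtype=float), 1.0 / sampling_rate)


def _signal_axes(recording: TrialRecording, keypoint: str, signal: str) -> np.ndarray:
    """Fetch (3, n) axis series for 'vel' or 'acc', deriving velocity from
    position when the exported velocity channels are absent."""
    if recording.has(keypoint, signal):
        return recording.get_axes(keypoint, signal)
    if signal == "vel" and recording.has(keypoint, "pos"):
        pos = recording.get_axes(keypoint, "pos")
        return np.stack(
            [derive_velocity(pos[i], recording.sampling_rate) for i in range(3)]
        )
    raise ChannelMissingError(
        f"recording '{recording.subject_id}' lacks {keypoint}_{signal}_[xyz]"
        + (" and has no position fallback" if signal == "vel" else "")
    )


def project_speed(
    recording: TrialRecording,
    keypoint: str,
    signal: str = "Vel",
    projection: str = "xyz",
    window: int = DEFAULT_WINDOW,
) -> SpeedSeries:
    """Smoothed, direction-projected speed series for one keypoint.

    Parameters
    ----------
    signal
        ``"Vel"`` (m/s) or ``"Acc"`` (m/s^2).
    projection
        ``"z"`` keeps the signed vertical component; ``"xy"`` is
        sqrt(x^2 + y^2); ``"xyz"`` is the full 3-D magnitude.
    window
        Odd moving-average window applied per axis before projection.
    """
    if projection not in PROJECTIONS:
        raise ValueError(f"projection must be one of {PROJECTIONS}, got {projection!r}")
    if signal not in SPEED_SIGNALS:
        raise ValueError(f"signal must be one of {tuple(SPEED_SIGNALS)}, got {signal!r}")
    axes = _signal_axes(recording, keypoint, SPEED_SIGNALS[signal])
    sm = np.stack([moving_average(axes[i], window) for i in range(3)])
    if projection == "z":
        values = sm[2]
    elif projection == "xy":
        values = np.hypot(sm[0], sm[1])
    else:
        values = np.sqrt(sm[0] ** 2 + sm[1] ** 2 + sm[2] ** 2)
    return SpeedSeries(
        keypoint=keypoint,
        projection=projection,
        signal=signal,
        values=values,
        sampling_rate=recording.sampling_rate,
    )
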