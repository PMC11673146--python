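"""Movement-phase segmentation from the pelvis vertical position.

A consultation-room trial contains exactly one sit: the subject walks in
standing, sits down, remains seated, stands up and walks out.  The pelvis
z trace therefore shows a high plateau, a monotone descent, a low plateau
and a monotone ascent.  The trial is split into four phases —
``Standing`` (including the walk-in), ``Sitting_down``, ``Sitting`` and
``Standing_up`` (including the walk-out) — at three boundaries:
sit-down onset (b1), seat-on (b2) and seat-off (b3).

Detection is two-stage.  A dual-threshold crossing with hysteresis locates
the single descent/ascent pair robustly (and rejects traces with no sit or
more than one sit).  Because any threshold on a smooth sigmoid-like
transition fires well after the true plateau departure, each boundary is
then refined by least-squares fitting a minimum-jerk-style smoothstep
profile to the transition region; the fitted onset/offset times are the
reported boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

PHASE_NAMES = ("Standing", "Sitting_down", "Sitting", "Standing_up")


class SegmentationError(ValueError):
    """The pelvis z trace does not match the single-sit protocol."""


class NoSitError(SegmentationError):
    """No seated plateau was detected."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds for the phase detector.

    delta
        Hysteresis depth as a fraction of the standing-to-seated amplitude.
    min_amplitude
        Minimum standing-to-seated z range (m) below which "no sit" is raised.
    min_phase_frames
        Minimum allowed phase length; 6 frames = 0.1 s at 60 frames/s.
    refine
        Whether to refine raw threshold crossings by smoothstep fitting.
    """

    delta: float = 0.15
    min_amplitude: float = 0.15
    min_phase_frames: int = 6
    refine: bool = True


@dataclass(frozen=True)
class PhaseSegmentation:
    """Three ordered boundaries partitioning [0, n_frames) into four phases."""

    boundaries: tuple[int, int, int]
    n_frames: int

    def __post_init__(self) -> None:
        b1, b2, b3 = self.boundaries
        if not (0 < b1 < b2 < b3 < self.n_frames):
            raise ValueError(
                f"boundaries must satisfy 0 < b1 < b2 < b3 < n_frames, "
                f"got {self.boundaries} with n_frames={self.n_frames}"
            )

    @property
    def phases(self) -> dict[str, tuple[int, int]]:
        """Half-open frame intervals; they partition [0, n_frames) exactly."""
        b1, b2, b3 = self.boundaries
        return {
            "Standing": (0, b1),
            "Sitting_down": (b1, b2),
            "Sitting": (b2, b3),
            "Standing_up": (b3, self.n_frames),
        }

    def durations_s(self, sampling_rate: float) -> dict[str, float]:
        return {
            name: (stop - start) / sampling_rate
            for name, (start, stop) in self.phases.items()
        }


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _fit_transition(
    z: np.ndarray, lo: int, hi: int, z_from: float, z_to: float,
    t0_guess: float, dur_guess: float,
) -> tuple[float, float] | None:
    """Fit z(t) = z_from + (z_to - z_from) * smoothstep((t - t0)/T) on
    frames [lo, hi); returns (t0, T) in frame units, or None on failure."""
    t = np.arange(lo, hi, dtype=float)
    seg = z[lo:hi]

    def model(tt, t0, dur, a, b):
        return a + (b - a) * _smoothstep((tt - t0) / dur)

    try:
        popt, _ = curve_fit(
            model,
            t,
            seg,
            p0=[t0_guess, max(dur_guess, 2.0), z_from, z_to],
            bounds=(
                [lo - len(seg), 1.0, -np.inf, -np.inf],
                [hi + len(seg), 4.0 * len(seg), np.inf, np.inf],
            ),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return None
    t0, dur = float(popt[0]), float(popt[1])
    if not np.isfinite(t0) or not np.isfinite(dur) or dur <= 0:
        return None
    return t0, dur


def segment_phases(
    pelvis_z,
    sampling_rate: float,
    config: SegmentationConfig | None = None,
) -> PhaseSegmentation:
    """Locate sit-down onset, seat-on and seat-off in a smoothed pelvis
    z-position series.

    Standing and seated levels are estimated as the medians of the top and
    bottom quartiles of z (robust to transition samples).  The descent is
    located by a downward crossing of the high hysteresis threshold followed
    by entry below the low threshold; the ascent by the subsequent upward
    recovery.  Boundaries are then refined by smoothstep fitting (see module
    docstring).

    Raises
    ------
    NoSitError
        If the z range is below ``min_amplitude`` or no seated plateau exists.
    SegmentationError
        If more than one seated plateau is present, or phases collapse below
        ``min_phase_frames``.
    """
    cfg = config or SegmentationConfig()
    z = np.asarray(pelvis_z, dtype=float)
    n = len(z)
    if n < 4 * cfg.min_phase_frames:
        raise SegmentationError(f"series too short to segment ({n} frames)")

    q25, q75 = np.quantile(z, [0.25, 0.75])
    z_stand = float(np.median(z[z >= q75]))
    z_sit = float(np.median(z[z <= q25]))
    amp = z_stand - z_sit
    if amp < cfg.min_amplitude:
        raise NoSitError(
            f"no sit detected: z range {amp:.3f} m below minimum "
            f"{cfg.min_amplitude} m"
        )
    high = z_stand - cfg.delta * amp
    low = z_sit + cfg.delta * amp

    # hysteresis pass: count seated plateaus (descents below `low` with a
    # full recovery above `high` in between)
    state_up = True
    plateaus = 0
    for value in z:
        if state_up and value < low:
            state_up = False
            plateaus += 1
        elif not state_up and value > high:
            state_up = True
    if plateaus == 0:
        raise NoSitError("no sit detected: trace never reaches the seated level")
    if plateaus > 1:
        raise SegmentationError(
            f"{plateaus} seated plateaus detected; the protocol assumes a single sit"
        )

    below_high = z < high
    c1 = int(np.argmax(below_high))  # first frame under the high threshold
    if not below_high[c1]:
        raise NoSitError("no sit detected")
    b1_raw = max(c1 - 1, 1)
    below_low = z < low
    c2 = c1 + int(np.argmax(below_low[c1:]))
    b2_raw = c2
    above_low = z[c2:] >= low
    if not above_low.any():
        raise SegmentationError("trace ends while still seated; no stand-up found")
    b3_raw = c2 + int(np.argmax(above_low))

    b1, b2, b3 = b1_raw, b2_raw, b3_raw
    if cfg.refine:
        span = max(b2_raw - b1_raw, 3)
        lo_d = max(0, b1_raw - 2 * span)
        hi_d = min(b3_raw, b2_raw + 2 * span)
        fit_down = _fit_transition(
            z, lo_d, hi_d, z_stand, z_sit,
            t0_guess=float(b1_raw) - 0.45 * span, dur_guess=1.9 * span,
        )
        if fit_down is not None:
            t0, dur = fit_down
            b1 = int(round(t0))
            b2 = int(round(t0 + dur))

        c4 = b3_raw + int(np.argmax(z[b3_raw:] > high)) if (z[b3_raw:] > high).any() else n - 1
        span_u = max(c4 - b3_raw, 3)
        lo_u = max(b2, b3_raw - 2 * span_u)
        hi_u = min(n, c4 + 2 * span_u)
        fit_up = _fit_transition(
            z, lo_u, hi_u, z_sit, z_stand,
            t0_guess=float(b3_raw) - 0.45 * span_u, dur_guess=1.9 * span_u,
        )
        if fit_up is not None:
            b3 = int(round(fit_up[0]))

        # refinement must stay consistent with the raw bracketing
        b1 = int(np.clip(b1, 1, b2_raw - 1))
        b2 = int(np.clip(b2, b1 + 1, b3_raw))
        b3 = int(np.clip(b3, b2 + 1, n - 1))

    seg = PhaseSegmentation(boundaries=(b1, b2, b3), n_frames=n)
    for name, (start, stop) in seg.phases.items():
        if stop - start < cfg.min_phase_frames:
            raise SegmentationError(
                f"phase {name} has {stop - start} frames, below the minimum "
                f"{cfg.min_phase_frames}"
            )
    return seg
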