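"""Synthetic consultation-room movement cohorts.

Generates virtual subjects performing the in-clinic protocol — walk about
2.5 m to a desk, sit down, remain seated through a brief conversation,
stand up and walk back — as multi-keypoint kinematic recordings, together
with timed-up-and-go (TUG) labels and SPPB component times.

Each subject carries a latent physical-function scalar ``function_level``
in (0, 1].  Fitter subjects walk faster and transit between sitting and
standing more quickly, which raises their peak speeds and hence the
standard deviation of their whole-trial pelvis speed (the PVV statistic);
the TUG label is linked hyperbolically to the same latent scalar
(``tug = intercept + slope / function_level + noise``), since time on a
fixed course scales with 1/speed and makes slow subjects disproportionately
slower.  Together these induce the negative PVV-vs-TUG correlation the
downstream analysis is built to recover, with a near-normal,
right-tailed TUG distribution spanning roughly 6 to over 20 s.

Trajectories are piecewise minimum-jerk-like smoothstep position segments;
velocity is the exact finite-difference derivative of position, with
per-frame Gaussian noise added afterwards.  Non-pelvis keypoints are the
pelvis trajectory plus fixed anatomical offsets and small smooth jitter —
plausible correlated company for the screening step, not a biomechanical
model.  Coordinates: x is the walking direction, z is vertical
(up-positive), metres and seconds throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AXES, DEFAULT_KEYPOINTS, TrialRecording, write_labels, write_trial
from .preprocessing import moving_average

logger = logging.getLogger(__name__)

#: Calibrated label-noise default (s): under the default cohort below this
#: yields a generative PVV-vs-TUG correlation of about -0.7.
DEFAULT_TUG_NOISE_SD = 2.25

#: Static keypoint offsets (m) relative to the pelvis, and jitter scales (m)
#: for the smooth positional noise that decorrelates secondary keypoints.
_KEYPOINT_OFFSETS: dict[str, tuple[float, float, float, float]] = {
    "Pelvis": (0.0, 0.0, 0.0, 0.0),
    "L5": (0.0, 0.0, 0.05, 0.012),
    "L3": (0.0, 0.0, 0.12, 0.015),
    "T12": (0.0, 0.0, 0.22, 0.018),
    "T8": (0.0, 0.0, 0.32, 0.022),
    "Neck": (0.0, 0.0, 0.55, 0.026),
    "Head": (0.0, 0.0, 0.70, 0.032),
    "RightShoulder": (0.0, -0.18, 0.50, 0.030),
    "RightUpperArm": (0.0, -0.20, 0.35, 0.045),
    "RightForearm": (0.0, -0.22, 0.12, 0.060),
    "RightHand": (0.0, -0.24, -0.05, 0.075),
    "LeftShoulder": (0.0, 0.18, 0.50, 0.030),
    "LeftUpperArm": (0.0, 0.20, 0.35, 0.045),
    "LeftForearm": (0.0, 0.22, 0.12, 0.060),
    "LeftHand": (0.0, 0.24, -0.05, 0.075),
    "RightUpperLeg": (0.0, -0.10, -0.25, 0.038),
    "RightLowerLeg": (0.0, -0.11, -0.60, 0.055),
    "RightFoot": (0.05, -0.12, -0.90, 0.070),
    "RightToe": (0.15, -0.12, -0.93, 0.075),
    "LeftUpperLeg": (0.0, 0.10, -0.25, 0.038),
    "LeftLowerLeg": (0.0, 0.11, -0.60, 0.055),
    "LeftFoot": (0.05, 0.12, -0.90, 0.070),
    "LeftToe": (0.15, 0.12, -0.93, 0.075),
}


@dataclass(frozen=True)
class TugLink:
    """Link from the latent function level to the TUG label (seconds)."""

    intercept: float = 4.0
    slope: float = 4.0
    noise_sd: float = DEFAULT_TUG_NOISE_SD


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject generative parameters."""

    subject_id: str
    function_level: float
    peak_walk_speed: float
    sit_duration: float
    transition_duration: float
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.function_level <= 1.0:
            raise ValueError("function_level must be in (0, 1]")
        if self.peak_walk_speed <= 0:
            raise ValueError("peak_walk_speed must be positive")
        if self.sit_duration <= 0 or self.transition_duration <= 0:
            raise ValueError("durations must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings."""

    n_subjects: int = 60
    sampling_rate: float = 60.0
    walk_distance: float = 2.5
    keypoints: tuple[str, ...] = DEFAULT_KEYPOINTS
    seed: int = 0
    tug_link: TugLink = field(default_factory=TugLink)
    stand_height: float = 0.95
    sit_height: float = 0.50
    max_trial_s: float = 120.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.walk_distance <= 0:
            raise ValueError("walk_distance must be positive")


@dataclass
class SyntheticTrial:
    """A generated trial with its ground truth."""

    recording: TrialRecording
    true_boundaries: tuple[int, int, int]  # sit-down onset, seat-on, seat-off
    true_function_level: float
    tug_label: float
    sppb_times: dict[str, float]

    def __post_init__(self) -> None:
        b1, b2, b3 = self.true_boundaries
        if not 0 < b1 < b2 < b3 < self.recording.n_frames:
            raise ValueError("true_boundaries must be strictly increasing in range")
        if self.tug_label <= 0:
            raise ValueError("tug_label must be positive")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def subject_params_from_function_level(
    function_level: float,
    subject_id: str,
    sit_duration: float = 10.0,
    noise_sd: float = 0.02,
) -> SubjectParams:
    """Map the latent function level to kinematic parameters.

    Peak walking speed rises linearly from 0.6 to 1.5 m/s over the (0, 1]
    range, bracketing typical self-selected speeds of older adults with
    impaired to preserved mobility.  The sit-stand transition is
    parameterized through its peak vertical speed, which — like any timed
    movement measure — is taken affine in 1/function_level; transitions
    thus lengthen from about 0.8 s (fit) to about 2.7 s (frail).
    """
    f = function_level
    # peak vertical speed of the sit-stand transfer, m/s
    v_z_peak = max(0.95 - 0.135 / f, 0.22)
    # smoothstep over duration T and height amp peaks at 1.5*amp/T
    transition = 1.5 * 0.45 / v_z_peak
    return SubjectParams(
        subject_id=subject_id,
        function_level=f,
        peak_walk_speed=0.6 + 0.9 * f,
        sit_duration=sit_duration,
        transition_duration=transition,
        noise_sd=noise_sd,
    )


def _pelvis_trajectory(
    params: SubjectParams,
    config: SimulationConfig,
    pauses: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5),
    gait_modulation: tuple[float, float, float] = (0.0, 2.0, 0.0),
    vigors: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Build the noiseless pelvis position (3, n) and true phase boundaries.

    ``pauses`` are the four standstill durations (s): before the walk-in,
    before sitting down, after standing up, and after the walk-out.
    ``gait_modulation`` is (relative amplitude, frequency Hz, phase) of the
    within-gait speed oscillation superimposed on the walking segments —
    per-step speed fluctuation, an idiosyncrasy not tied to function level.
    ``vigors`` are speed multipliers for the four movement bouts (walk-in,
    sit-down, stand-up, walk-out): nobody executes two bouts at exactly the
    same briskness, so each bout draws its own within-subject factor.
    """
    fps = config.sampling_rate
    n_pauses = [max(int(round(p * fps)), 1) for p in pauses]
    # smoothstep over T has peak velocity 1.5 * distance / T
    walk_dur = 1.5 * config.walk_distance / params.peak_walk_speed
    n_walk_in = max(int(round(walk_dur / vigors[0] * fps)), 2)
    n_walk_out = max(int(round(walk_dur / vigors[3] * fps)), 2)
    n_trans_down = max(int(round(params.transition_duration / vigors[1] * fps)), 2)
    n_trans_up = max(int(round(params.transition_duration / vigors[2] * fps)), 2)
    n_sit = max(int(round(params.sit_duration * fps)), 2)

    lengths = [n_pauses[0], n_walk_in, n_pauses[1], n_trans_down, n_sit,
               n_trans_up, n_pauses[2], n_walk_out, n_pauses[3]]
    total = sum(lengths)
    if total / fps > config.max_trial_s:
        raise ValueError(
            f"sit/transition durations produce a {total / fps:.0f} s trial, "
            f"longer than max_trial_s={config.max_trial_s}"
        )
    starts = np.cumsum([0] + lengths[:-1])
    b1 = int(starts[3])  # sit-down onset
    b2 = int(starts[4])  # seat-on
    b3 = int(starts[5])  # seat-off

    x = np.empty(total)
    z = np.empty(total)
    d = config.walk_distance
    amp_rel, freq, phase = gait_modulation
    # positional amplitude giving a velocity oscillation of amp_rel * peak
    wobble_amp = amp_rel * params.peak_walk_speed / (2.0 * np.pi * freq)
    x_rest = [0.0, None, d, d, d, d, d, None, 0.0]
    for i, (start, length) in enumerate(zip(starts, lengths)):
        sl = slice(start, start + length)
        u = np.arange(length) / length
        if i in (1, 7):
            base = d * _smoothstep(u) if i == 1 else d * (1.0 - _smoothstep(u))
            t = (np.arange(start, start + length)) / fps
            # sin(pi*u) envelope keeps the walk endpoints stationary
            x[sl] = base + wobble_amp * np.sin(2 * np.pi * freq * t + phase) * np.sin(np.pi * u)
        else:
            x[sl] = x_rest[i]
        if i == 3:
            z[sl] = config.stand_height - (config.stand_height - config.sit_height) * _smoothstep(u)
        elif i == 4:
            z[sl] = config.sit_height
        elif i == 5:
            z[sl] = config.sit_height + (config.stand_height - config.sit_height) * _smoothstep(u)
        else:
            z[sl] = config.stand_height
    y = np.zeros(total)
    return np.stack([x, y, z]), (b1, b2, b3)


def _smooth_noise(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """Band-limited positional jitter: smoothed white noise."""
    if scale == 0.0:
        return np.zeros(n)
    return moving_average(rng.normal(0.0, scale, n), 9 if n >= 9 else 1)


def _sppb_times(
    f: float, params: SubjectParams, rng: np.random.Generator
) -> dict[str, float]:
    """SPPB component times with a ceiling for fit subjects.

    Balance holds are 10 s minus an exponential deficit scaled by
    (1 - function_level), with a small grace margin absorbed before the hold
    is cut short — fit subjects therefore complete the full 10 s hold,
    reproducing the clinical ceiling where many subjects score a perfect 12.
    """
    holds = {}
    for stance, hardness in (("side_by_side", 0.6), ("semi_tandem", 1.0), ("tandem", 1.6)):
        deficit = (1.0 - f) * rng.exponential(1.2) * hardness
        holds[stance] = 10.0 if deficit <= 1.0 else max(0.0, 11.0 - deficit)
    walk4m = 4.0 / (0.55 + 0.75 * f) + abs(rng.normal(0.0, 0.2))
    sts5 = 5.0 * (1.2 + 1.8 * (1.0 - f)) + abs(rng.normal(0.0, 0.5))
    return {**holds, "walk4m": walk4m, "sts5": sts5}


def simulate_trajectory(
    params: SubjectParams,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticTrial:
    """Generate one subject's trial recording plus labels and ground truth.

    For every configured keypoint the recording holds position, velocity and
    acceleration in x, y, z at ``config.sampling_rate``.  Velocity is the
    central finite difference of position (so a noiseless trial satisfies
    the velocity/position consistency invariant exactly); Gaussian noise of
    sd ``params.noise_sd`` is then added per frame to velocity and
    acceleration channels.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    fps = config.sampling_rate
    pauses = tuple(rng.uniform(0.2, 2.0, 4))
    gait_modulation = (
        float(rng.uniform(0.05, 0.30)),
        float(rng.uniform(1.2, 2.2)),
        float(rng.uniform(0.0, 2.0 * np.pi)),
    )
    walk_vigors = np.clip(rng.normal(1.0, 0.12, 2), 0.7, 1.4)
    trans_vigors = np.clip(rng.normal(1.0, 0.22, 2), 0.6, 1.5)
    vigors = (walk_vigors[0], trans_vigors[0], trans_vigors[1], walk_vigors[1])
    pelvis_pos, boundaries = _pelvis_trajectory(
        params, config, pauses, gait_modulation, vigors
    )
    n = pelvis_pos.shape[1]
    t = np.arange(n) / fps

    channels: dict[tuple[str, str, str], np.ndarray] = {}
    for kp in config.keypoints:
        off_x, off_y, off_z, sway = _KEYPOINT_OFFSETS.get(kp, (0.0, 0.0, 0.0, 0.03))
        pos = pelvis_pos + np.array([[off_x], [off_y], [off_z]])
        if kp != "Pelvis":
            # idiosyncratic segment motion (arm swing, head sway, ...):
            # per-subject random amplitude and rhythm, uncorrelated with
            # function level, plus band-limited positional jitter
            gain = rng.uniform(0.4, 1.6)
            freqs = rng.uniform(0.6, 2.5, 2)
            phases = rng.uniform(0.0, 2.0 * np.pi, 2)
            sway_xy = np.stack(
                [
                    sway * gain * np.sin(2 * np.pi * freqs[0] * t + phases[0]),
                    0.8 * sway * gain * np.sin(2 * np.pi * freqs[1] * t + phases[1]),
                    np.zeros(n),
                ]
            )
            jitter = np.stack([_smooth_noise(rng, n, 0.3 * sway) for _ in range(3)])
            pos = pos + sway_xy + jitter
        vel = np.gradient(pos, 1.0 / fps, axis=1)
        acc = np.gradient(vel, 1.0 / fps, axis=1)
        if params.noise_sd > 0:
            vel = vel + rng.normal(0.0, params.noise_sd, vel.shape)
            acc = acc + rng.normal(0.0, params.noise_sd * fps * 0.05, acc.shape)
        for i, ax in enumerate(AXES):
            channels[(kp, "pos", ax)] = pos[i]
            channels[(kp, "vel", ax)] = vel[i]
            channels[(kp, "acc", ax)] = acc[i]

    link = config.tug_link
    f = params.function_level
    tug = link.intercept + link.slope / f
    if link.noise_sd > 0:
        tug += rng.normal(0.0, link.noise_sd)
    tug = max(tug, 1.0)

    recording = TrialRecording(
        subject_id=params.subject_id, sampling_rate=fps, channels=channels
    )
    return SyntheticTrial(
        recording=recording,
        true_boundaries=boundaries,
        true_function_level=f,
        tug_label=float(tug),
        sppb_times=_sppb_times(f, params, rng),
    )


def simulate_cohort(
    config: SimulationConfig,
    function_level_range: tuple[float, float] = (0.25, 1.0),
) -> list[SyntheticTrial]:
    """Generate a cohort of trials with TUG labels linked to function level.

    Function levels are drawn uniformly over ``function_level_range``; the
    hyperbolic TUG link then produces a near-normal distribution with a
    right tail.  With small link noise the cohort has a negative sample
    correlation between whole-trial pelvis speed SD and the TUG label.
    """
    if config.n_subjects < 2:
        raise ValueError("simulate_cohort needs n_subjects >= 2")
    lo, hi = function_level_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("function_level_range must satisfy 0 < lo <= hi <= 1")
    if lo == hi:
        logger.warning(
            "degenerate function_level_range (%s): no label variance to model", lo
        )
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects + 1)
    rng0 = np.random.default_rng(children[0])
    trials = []
    for i in range(config.n_subjects):
        f = lo if lo == hi else float(rng0.uniform(lo, hi))
        sit = float(rng0.uniform(9.0, 11.0))
        params = subject_params_from_function_level(
            f, subject_id=f"S{i:03d}", sit_duration=sit
        )
        trials.append(
            simulate_trajectory(params, config, rng=np.random.default_rng(children[i + 1]))
        )
    return trials


def tug_noise_for_target_r(
    config: SimulationConfig,
    target_r: float = -0.7,
    function_level_range: tuple[float, float] = (0.25, 1.0),
    n_mc: int = 200,
    seed: int | None = None,
) -> float:
    """Label-noise sd that makes the generative corr(PVV, TUG) hit a target.

    With noiseless labels h(f) = intercept + slope/f, adding independent
    Gaussian noise of sd sigma attenuates the PVV-TUG correlation to
    rho0 * sd(h) / sqrt(sd(h)^2 + sigma^2), where rho0 = corr(PVV, h).
    Both rho0 and sd(h) are estimated by Monte Carlo over ``n_mc`` simulated
    trials on a function-level grid, then the equation is inverted.
    """
    from .preprocessing import project_speed

    if not 0.0 < abs(target_r) < 1.0:
        raise ValueError("target_r must have magnitude in (0, 1)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = function_level_range
    levels = np.linspace(lo, hi, n_mc)
    link = config.tug_link
    pvv = np.empty(n_mc)
    h = link.intercept + link.slope / levels
    mc_config = replace(config, keypoints=("Pelvis",))
    for i, f in enumerate(levels):
        params = subject_params_from_function_level(
            float(f), subject_id=f"MC{i:03d}", sit_duration=float(rng.uniform(9.0, 11.0))
        )
        trial = simulate_trajectory(params, mc_config, rng=rng)
        speed = project_speed(trial.recording, "Pelvis", "Vel", "xyz").values
        pvv[i] = speed.std()
    rho0 = float(np.corrcoef(pvv, h)[0, 1])
    sd_h = float(h.std())
    if rho0**2 <= target_r**2:
        raise ValueError(
            f"target |r|={abs(target_r):.2f} exceeds the noiseless ceiling "
            f"|rho0|={abs(rho0):.2f}"
        )
    return sd_h * float(np.sqrt(rho0**2 / target_r**2 - 1.0))


def write_cohort(trials: list[SyntheticTrial], directory: str | Path) -> Path:
    """Write trials, labels and ground truth under ``directory``.

    Layout: ``trials/<subject_id>.csv`` per trial, ``labels.csv`` with
    subject_id, tug_s and SPPB component times, and ``ground_truth.json``
    with phase boundaries and function levels for tests.
    """
    directory = Path(directory)
    (directory / "trials").mkdir(parents=True, exist_ok=True)
    rows = []
    truth = {}
    for trial in trials:
        sid = trial.recording.subject_id
        write_trial(trial.recording, directory / "trials" / f"{sid}.csv")
        rows.append(
            {
                "subject_id": sid,
                "tug_s": trial.tug_label,
                "walk4m_s": trial.sppb_times["walk4m"],
                "sts5_s": trial.sppb_times["sts5"],
                "side_by_side_s": trial.sppb_times["side_by_side"],
                "semi_tandem_s": trial.sppb_times["semi_tandem"],
                "tandem_s": trial.sppb_times["tandem"],
            }
        )
        truth[sid] = {
            "boundaries": list(trial.true_boundaries),
            "function_level": trial.true_function_level,
        }
    write_labels(pd.DataFrame(rows), directory / "labels.csv")
    (directory / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return directory
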