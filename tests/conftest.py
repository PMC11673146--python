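"""Shared fixtures, including the cohort-level recovery experiment.

The recovery experiment (20 independent synthetic cohorts of 60 subjects,
label noise calibrated so the generative PVV-vs-TUG correlation is -0.7)
is expensive, so it runs once per session and several tests assert
different properties of its results.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pytest

from pvv.features import PVV_FEATURE, build_pelvis_features, pearson_r, screen_keypoints
from pvv.io import KeypointRegistry
from pvv.modeling import SelectionConfig, fit_final_single_feature, run_selection
from pvv.preprocessing import moving_average, project_speed
from pvv.segmentation import segment_phases
from pvv.synthetic import (
    SimulationConfig,
    TugLink,
    simulate_cohort,
    simulate_trajectory,
    subject_params_from_function_level,
    tug_noise_for_target_r,
)

N_RECOVERY_SEEDS = 20


@pytest.fixture(scope="session")
def small_registry() -> KeypointRegistry:
    return KeypointRegistry(("Pelvis", "T8", "Head"))


@pytest.fixture(scope="session")
def pelvis_config() -> SimulationConfig:
    """Single-keypoint simulation config for cheap kinematic tests."""
    return SimulationConfig(n_subjects=2, seed=0, keypoints=("Pelvis",))


@pytest.fixture()
def noiseless_trial(pelvis_config):
    params = subject_params_from_function_level(0.7, "S000", noise_sd=0.0)
    return simulate_trajectory(params, pelvis_config, rng=np.random.default_rng(5))


@dataclass
class SeedResult:
    final_feature: str
    selection_sizes: list[int]
    pvv_fold_count: int
    top3_keypoints: list[str]
    slopes: np.ndarray
    pooled_r: float
    pvv_tug_r: float


@pytest.fixture(scope="session")
def recovery_experiment() -> list[SeedResult]:
    """Full-chain parameter recovery on 20 independent synthetic cohorts.

    Study conditions: n = 60 subjects per cohort, TUG label noise calibrated
    once so that the generative correlation between pelvis velocity
    variability and TUG is -0.7.  Each seed runs screening, segmentation,
    the 120-feature table, per-fold Lasso selection with frequency analysis,
    and the final univariate fit on PVV.
    """
    base = SimulationConfig(seed=0)
    noise_sd = tug_noise_for_target_r(base, target_r=-0.7, seed=0)
    link = TugLink(noise_sd=noise_sd)

    results = []
    for seed in range(N_RECOVERY_SEEDS):
        config = replace(base, seed=seed, tug_link=link)
        trials = simulate_cohort(config)
        cohort = [t.recording for t in trials]
        tug = np.array([t.tug_label for t in trials])

        screening = screen_keypoints(cohort, tug)
        top3 = list(dict.fromkeys(screening["keypoint"]))[:3]

        segs = {
            rec.subject_id: segment_phases(
                moving_average(rec.get_axes("Pelvis", "pos")[2], 5),
                rec.sampling_rate,
            )
            for rec in cohort
        }
        table = build_pelvis_features(cohort, segs, tug).impute_missing()
        selection = run_selection(table, SelectionConfig(seed=seed))
        result = fit_final_single_feature(table, PVV_FEATURE, SelectionConfig(seed=seed))

        results.append(
            SeedResult(
                final_feature=selection.final_feature,
                selection_sizes=[len(fs.coefficients) for fs in selection.per_fold],
                pvv_fold_count=int(selection.frequency.get(PVV_FEATURE, 0)),
                top3_keypoints=top3,
                slopes=result.per_fold["slope"].to_numpy(),
                pooled_r=result.pooled_r,
                pvv_tug_r=pearson_r(table.values[PVV_FEATURE], tug),
            )
        )
    return results
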