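"""Correlation screening and the 120-feature pelvis table."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvv.features import (
    PVV_FEATURE,
    build_pelvis_features,
    coefficient_of_variation,
    feature_names,
    pearson_r,
    screen_keypoints,
)
from pvv.io import KeypointRegistry, TrialRecording
from pvv.segmentation import PhaseSegmentation, segment_phases
from pvv.preprocessing import moving_average
from pvv.synthetic import SimulationConfig, simulate_cohort

NAME_RE = re.compile(
    r"^(z|xy|xyz)_(Max|Min|Mean|SD)_(Vel|Acc)_"
    r"(Standing|Sitting_down|Sitting|Standing_up|Throughout)$"
)


@pytest.fixture(scope="module")
def small_cohort():
    config = SimulationConfig(n_subjects=6, seed=11, keypoints=("Pelvis", "T8", "Head"))
    trials = simulate_cohort(config)
    cohort = [t.recording for t in trials]
    labels = np.array([t.tug_label for t in trials])
    segs = {
        r.subject_id: segment_phases(
            moving_average(r.get_axes("Pelvis", "pos")[2], 5), r.sampling_rate
        )
        for r in cohort
    }
    return cohort, segs, labels


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_summation_formula(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=10), rng.normal(size=10)
        n = len(x)
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(
            n * (y**2).sum() - y.sum() ** 2
        )
        assert pearson_r(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_raises_not_silent_zero(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_length_mismatch_and_short_series_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="3 points"):
            pearson_r([1, 2], [3, 4])


class TestCoV:
    def test_sd_over_mean(self):
        x = np.array([0.8, 1.2, 0.8, 1.2])
        assert coefficient_of_variation(x) == pytest.approx(0.2)

    def test_matches_independent_computation(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1.0, 3.0, 50)
        expected = float(np.std(x)) / float(np.mean(x))
        assert coefficient_of_variation(x) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0.1, 1000.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_invariance(self, k):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert coefficient_of_variation(k * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-9
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero mean"):
            coefficient_of_variation([-1.0, 1.0])


class TestFeatureTable:
    def test_scheme_has_exactly_120_unique_wellformed_names(self):
        names = feature_names()
        assert len(names) == 120
        assert len(set(names)) == 120
        assert all(NAME_RE.match(n) for n in names)
        assert PVV_FEATURE in names

    def test_built_table_has_all_columns(self, small_cohort):
        cohort, segs, labels = small_cohort
        table = build_pelvis_features(cohort, segs, labels)
        assert list(table.values.columns) == feature_names()
        assert (table.values[PVV_FEATURE] >= 0).all()

    def test_constant_speed_collapses_statistics(self):
        n = 120
        channels = {}
        for ax, v in zip(("x", "y", "z"), (3.0, 4.0, 0.0)):
            channels[("Pelvis", "vel", ax)] = np.full(n, v)
            channels[("Pelvis", "acc", ax)] = np.zeros(n)
        rec = TrialRecording(subject_id="c", sampling_rate=60.0, channels=channels)
        seg = PhaseSegmentation(boundaries=(30, 60, 90), n_frames=n)
        table = build_pelvis_features([rec], {"c": seg}, [10.0])
        row = table.values.iloc[0]
        for stat in ("Max", "Min", "Mean"):
            assert row[f"xy_{stat}_Vel_Throughout"] == pytest.approx(5.0)
        assert row["xy_SD_Vel_Throughout"] == pytest.approx(0.0)
        assert row[PVV_FEATURE] == pytest.approx(0.0)

    def test_pvv_column_matches_two_pass_sd(self, small_cohort):
        from pvv.preprocessing import project_speed

        cohort, segs, labels = small_cohort
        table = build_pelvis_features(cohort, segs, labels)
        rec = cohort[0]
        speed = project_speed(rec, "Pelvis", "Vel", "xyz", 5).values
        mean = sum(speed) / len(speed)
        sd = (sum((s - mean) ** 2 for s in speed) / len(speed)) ** 0.5
        assert table.values.loc[rec.subject_id, PVV_FEATURE] == pytest.approx(
            sd, abs=1e-9
        )

    def test_moment_orderings_hold_per_subject_and_phase(self, small_cohort):
        cohort, segs, labels = small_cohort
        row_frame = build_pelvis_features(cohort, segs, labels).values
        for d in ("z", "xy", "xyz"):
            for sig in ("Vel", "Acc"):
                for phase in ("Standing", "Sitting", "Throughout"):
                    mx = row_frame[f"{d}_Max_{sig}_{phase}"]
                    mn = row_frame[f"{d}_Min_{sig}_{phase}"]
                    mean = row_frame[f"{d}_Mean_{sig}_{phase}"]
                    sd = row_frame[f"{d}_SD_{sig}_{phase}"]
                    assert (mn <= mean + 1e-12).all() and (mean <= mx + 1e-12).all()
                    assert (sd >= 0).all()
                    if d != "z":
                        assert (mn >= 0).all()

    def test_throughout_extremes_bound_phase_extremes(self, small_cohort):
        cohort, segs, labels = small_cohort
        row_frame = build_pelvis_features(cohort, segs, labels).values
        phases = ("Standing", "Sitting_down", "Sitting", "Standing_up")
        for d in ("xy", "xyz"):
            phase_max = row_frame[[f"{d}_Max_Vel_{p}" for p in phases]].max(axis=1)
            phase_min = row_frame[[f"{d}_Min_Vel_{p}" for p in phases]].min(axis=1)
            np.testing.assert_allclose(
                row_frame[f"{d}_Max_Vel_Throughout"], phase_max, atol=1e-12
            )
            np.testing.assert_allclose(
                row_frame[f"{d}_Min_Vel_Throughout"], phase_min, atol=1e-12
            )

    def test_rebuild_is_bit_identical(self, small_cohort):
        cohort, segs, labels = small_cohort
        a = build_pelvis_features(cohort, segs, labels).values
        b = build_pelvis_features(cohort, segs, labels).values
        assert a.equals(b)

    def test_missing_phase_features_are_imputed_with_median(self, small_cohort):
        cohort, segs, labels = small_cohort
        table = build_pelvis_features(cohort, segs, labels)
        table.values.iloc[0, 3] = np.nan
        filled = table.impute_missing()
        assert not filled.values.isna().any().any()
        col = table.values.columns[3]
        assert filled.values.iloc[0, 3] == pytest.approx(
            table.values[col].median()
        )


class TestScreening:
    def test_reports_top_k_ranked_by_abs_r(self, small_cohort):
        cohort, _, labels = small_cohort
        report = screen_keypoints(
            cohort, labels, KeypointRegistry(("Pelvis", "T8", "Head")), top_k=5
        )
        assert len(report) == 5
        assert (report["abs_r"].diff().dropna() <= 1e-12).all()
        assert set(report["statistic"]) <= {"Max", "Min", "Mean"}

    def test_identical_recordings_propagate_zero_variance_error(self, small_cohort):
        cohort, _, labels = small_cohort
        clones = [cohort[0]] * 4
        with pytest.raises(ValueError, match="zero variance"):
            screen_keypoints(
                clones, labels[:4], KeypointRegistry(("Pelvis", "T8", "Head"))
            )

    def test_missing_keypoint_is_skipped_with_warning(self, small_cohort, caplog):
        cohort, _, labels = small_cohort
        registry = KeypointRegistry(("Pelvis", "T8", "Head", "Neck"))
        with caplog.at_level("WARNING", logger="pvv.features"):
            report = screen_keypoints(cohort, labels, registry, top_k=100)
        assert "Neck" not in set(report["keypoint"])
        assert any("Neck" in rec.message for rec in caplog.records)

    def test_pelvis_ranks_among_top_keypoints(self, recovery_experiment):
        """The keypoint that drives the label should screen into the top 3
        by |r| in nearly every cohort replicate."""
        hits = sum("Pelvis" in res.top3_keypoints for res in recovery_experiment)
        assert hits >= 18

    def test_pvv_tug_correlation_has_generative_sign(self, recovery_experiment):
        negatives = sum(res.pvv_tug_r < 0 for res in recovery_experiment)
        assert negatives >= 19
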