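"""Motion-track generators, resampling, discretization and pose summaries."""

import numpy as np
import pytest

from motionsampling import (
    MotionTrack,
    RigidPose,
    discretize_states,
    fraction_in_motion,
    load_track_tsv,
    make_drift,
    make_instantaneous,
    make_realistic,
    peak_to_peak,
    resample_track,
    rms_displacement,
    save_track_tsv,
)
from motionsampling.motion import RealisticProfile, state_labels


class TestInstantaneous:
    def test_half_split_levels(self):
        track = make_instantaneous(100, 10.0, "x", (0.5,))
        assert np.all(track.rotations[:50, 0] == -10.0)
        assert np.all(track.rotations[50:, 0] == 10.0)
        assert np.all(track.rotations[:, 1:] == 0.0)

    def test_mean_pose_normalization_of_10_90_split(self):
        # 10% at -10 deg, 90% at +10 deg: occupancy-weighted mean is +8, so
        # the mean-referenced states are -18 and +2 degrees
        track = make_instantaneous(1000, 10.0, "x", (0.1,)).to_mean_reference()
        assert track.rotations[0, 0] == pytest.approx(-18.0)
        assert track.rotations[-1, 0] == pytest.approx(2.0)

    def test_zero_amplitude_is_identity(self):
        track = make_instantaneous(50, 0.0, "x")
        assert np.all(track.rotations == 0) and np.all(track.translations == 0)

    @pytest.mark.parametrize("fractions", [(0.0,), (1.0,), (0.6, 0.4), (0.5, 0.5)])
    def test_bad_switch_fractions_rejected(self, fractions):
        with pytest.raises(ValueError):
            make_instantaneous(100, 10.0, "x", fractions)

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError):
            make_instantaneous(100, 10.0, "w")


class TestDrift:
    def test_linear_ramp_midpoint_and_endpoints(self):
        track = make_drift(101, 5.0, "x")
        assert track.rotations[50, 0] == pytest.approx(0.0, abs=1e-12)
        assert track.rotations[0, 0] == -5.0
        assert track.rotations[-1, 0] == 5.0

    def test_discretized_ramp_is_the_100_point_grid(self):
        track = discretize_states(make_drift(10000, 10.0, "x"), 100)
        levels = np.unique(track.rotations[:, 0])
        assert len(levels) == 100
        np.testing.assert_allclose(np.diff(levels), np.diff(levels)[0], rtol=1e-9)
        counts = np.bincount(state_labels(track))
        assert np.all(counts == 100)  # each state spans 1% of readouts


class TestResample:
    def test_stretch_preserves_value_set_and_extremes(self):
        track = make_drift(25600, 5.0, "x")
        out = resample_track(track, 40320)
        assert out.n_readouts == 40320
        src = set(np.round(track.rotations[:, 0], 12))
        assert set(np.round(out.rotations[:, 0], 12)) <= src
        assert out.rotations[:, 0].min() == track.rotations[:, 0].min()
        assert out.rotations[:, 0].max() == track.rotations[:, 0].max()

    def test_same_length_is_identity(self):
        track = make_drift(100, 5.0)
        out = resample_track(track, 100)
        np.testing.assert_array_equal(out.rotations, track.rotations)

    def test_constant_track_stays_constant(self):
        track = MotionTrack(np.tile([3.0, 0, 0], (7, 1)), np.zeros((7, 3)))
        out = resample_track(track, 31)
        assert np.all(out.rotations[:, 0] == 3.0)

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            resample_track(make_drift(10, 1.0), 0)


class TestRealistic:
    def test_reproducible_from_seed(self):
        a = make_realistic(5000, seed=11)
        b = make_realistic(5000, seed=11)
        np.testing.assert_array_equal(a.rotations, b.rotations)
        np.testing.assert_array_equal(a.translations, b.translations)

    def test_quiescent_profile_is_constant(self):
        profile = RealisticProfile(motion_fraction=0.0, drift_step_deg=0.0, jump_rate=0.0)
        track = make_realistic(2000, seed=0, profile=profile)
        assert np.all(np.diff(track.rotations, axis=0) == 0.0)

    def test_pediatric_statistics_converge_to_profile_targets(self):
        # averaged over 50 seeds the generated tracks match the profile's
        # pediatric-scale targets within 20% relative
        profile = RealisticProfile()
        p2p, fim = [], []
        for seed in range(50):
            track = make_realistic(25600, seed=seed)
            p2p.append(peak_to_peak(track, "pitch"))
            fim.append(fraction_in_motion(track))
        assert abs(np.mean(p2p) - profile.peak_to_peak_deg) / profile.peak_to_peak_deg < 0.2
        assert abs(np.mean(fim) - profile.motion_fraction) / profile.motion_fraction < 0.2
        # pediatric-scale motion: large excursions, >11% of readouts in motion
        assert np.mean(p2p) >= 13.0
        assert np.mean(fim) >= 0.11

    def test_pitch_dominant(self):
        spans = np.zeros(3)
        for seed in range(20):
            t = make_realistic(10000, seed=seed)
            spans += t.rotations.max(axis=0) - t.rotations.min(axis=0)
        assert spans[0] > spans[1] and spans[0] > spans[2]


class TestDiscretize:
    def test_two_pose_track_survives_as_two_states(self):
        track = make_instantaneous(1000, 10.0, "x", (0.5,))
        out = discretize_states(track, 100)
        assert len(np.unique(out.rotations[:, 0])) == 2

    def test_single_state_is_mean_pose(self):
        track = make_drift(100, 10.0, "x")
        out = discretize_states(track, 1)
        expected = np.tile(track.rotations.mean(axis=0), (100, 1))
        np.testing.assert_allclose(out.rotations, expected, atol=1e-12)

    def test_invalid_state_count_rejected(self):
        with pytest.raises(ValueError):
            discretize_states(make_drift(10, 1.0), 0)


class TestMeanReference:
    def test_idempotent_and_shift_only(self):
        track = make_realistic(2000, seed=5)
        ref = track.to_mean_reference()
        assert ref.reference == "mean_pose"
        np.testing.assert_allclose(ref.rotations.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(
            ref.to_mean_reference().rotations, ref.rotations, atol=1e-12
        )
        # pairwise pose differences are invariant under re-referencing
        np.testing.assert_allclose(
            np.diff(ref.rotations, axis=0), np.diff(track.rotations, axis=0), atol=1e-12
        )


class TestRmsDisplacement:
    def test_identity_pose_zero(self):
        assert rms_displacement(RigidPose()) == 0.0

    def test_pure_translation(self):
        assert rms_displacement(RigidPose(translations=(3.0, 0, 0))) == pytest.approx(3.0)

    def test_closed_form_matches_monte_carlo_over_sphere(self):
        # oracle: average |displacement|^2 over points uniform in a 64 mm
        # spherical head volume
        pose = RigidPose((10.0, 0.0, 0.0))
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(100_000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= 64.0 * rng.uniform(size=(len(pts), 1)) ** (1.0 / 3.0)
        moved = pts @ pose.rotation_matrix().T
        mc = np.sqrt(np.mean(np.sum((moved - pts) ** 2, axis=1)))
        assert rms_displacement(pose, 64.0) == pytest.approx(mc, rel=2e-3)

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            rms_displacement(RigidPose(), 0.0)


def test_tsv_round_trip(tmp_path):
    track = make_realistic(500, seed=2)
    path = tmp_path / "track.tsv"
    save_track_tsv(track, path)
    back = load_track_tsv(path)
    np.testing.assert_allclose(back.rotations, track.rotations, atol=1e-9)
    np.testing.assert_allclose(back.translations, track.translations, atol=1e-9)
    assert path.read_text().splitlines()[0].split("\t") == [
        "readout", "rx", "ry", "rz", "tx", "ty", "tz",
    ]


def test_track_shape_validation():
    with pytest.raises(ValueError):
        MotionTrack(np.zeros((5, 3)), np.zeros((4, 3)))
    with pytest.raises(ValueError):
        MotionTrack(np.zeros((5, 2)), np.zeros((5, 2)))
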