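"""Motion-corrupted k-space synthesis against per-state brute-force oracles."""

import numpy as np
import pytest

from motionsampling import (
    cartesian_trajectory,
    forward_model,
    kooshball_trajectory,
    load_kspace_h5,
    save_kspace_h5,
    simulate_motion_corrupted,
)
from motionsampling.motion import MotionTrack, make_instantaneous
from motionsampling.nufft import dft3_direct
from motionsampling.phantom import RigidPose, rotate_about_grid_center
from motionsampling.trajectory import Trajectory

from conftest import constant_track, zero_track


class TestForwardModel:
    def test_centered_impulse_has_flat_magnitude(self):
        n = 16
        vol = np.zeros((n, n, n))
        vol[n // 2, n // 2, n // 2] = 2.0
        coords = np.random.default_rng(0).uniform(-n / 2, n / 2, size=(40, 3))
        out = forward_model(vol, coords)
        np.testing.assert_allclose(np.abs(out), 2.0, rtol=1e-6)

    def test_dc_sample_is_volume_sum(self, phantom16):
        out = forward_model(phantom16, np.zeros((1, 3)))
        assert out[0] == pytest.approx(phantom16.sum(), rel=1e-9)

    def test_out_of_ball_coords_rejected(self, phantom16):
        with pytest.raises(ValueError):
            forward_model(phantom16, np.array([[20.0, 0.0, 0.0]]))

    def test_nufft_path_matches_brute_force(self):
        rng = np.random.default_rng(5)
        vol = rng.normal(size=(16, 16, 16))
        coords = rng.uniform(-8, 8, size=(50, 3))
        fast = forward_model(vol, coords, method="nufft")
        ref = dft3_direct(vol.astype(complex), coords)
        assert np.max(np.abs(fast - ref) / np.abs(ref)) <= 1e-5


class TestSimulate:
    def test_zero_motion_reduces_to_forward_model(self, phantom16):
        traj = cartesian_trajectory(16)
        kdata = simulate_motion_corrupted(phantom16, traj, zero_track(traj.n_readouts))
        expected = forward_model(phantom16, traj.coords)
        np.testing.assert_allclose(kdata.samples, expected, rtol=1e-12)
        assert kdata.n_transforms == 1

    def test_constant_pose_equals_posed_phantom_kspace(self, phantom16):
        traj = kooshball_trajectory(16)
        pose = RigidPose((6.0, 0.0, 0.0))
        kdata = simulate_motion_corrupted(
            phantom16, traj, constant_track(traj.n_readouts, (6.0, 0.0, 0.0))
        )
        posed = rotate_about_grid_center(phantom16, pose)
        np.testing.assert_allclose(kdata.samples, forward_model(posed, traj.coords), rtol=1e-12)

    def test_two_state_track_matches_per_state_oracle(self, phantom16):
        # 20 readouts, 2-state instantaneous flip: every readout must match the
        # brute-force spectrum of the correspondingly posed phantom
        rng = np.random.default_rng(7)
        coords = rng.uniform(-8, 8, size=(20, 5, 3))
        traj = Trajectory(coords, "kooshball", "non_smooth", 16)
        track = make_instantaneous(20, 8.0, "x", (0.5,))
        kdata = simulate_motion_corrupted(phantom16, traj, track, n_states=100)
        for pose_angle, sl in [(-8.0, slice(0, 10)), (8.0, slice(10, 20))]:
            posed = rotate_about_grid_center(phantom16, RigidPose((pose_angle, 0, 0)))
            ref = dft3_direct(posed.astype(complex), coords[sl].reshape(-1, 3))
            got = kdata.samples[sl].reshape(-1)
            assert np.max(np.abs(got - ref)) / np.max(np.abs(ref)) <= 1e-5
        assert kdata.n_transforms == 2

    def test_linearity_in_the_phantom(self, phantom16):
        rng = np.random.default_rng(8)
        other = rng.normal(size=phantom16.shape)
        traj = kooshball_trajectory(16)
        track = make_instantaneous(traj.n_readouts, 5.0, "y", (0.3,))
        a = simulate_motion_corrupted(phantom16, traj, track).samples
        b = simulate_motion_corrupted(other, traj, track).samples
        ab = simulate_motion_corrupted(phantom16 + 2.0 * other, traj, track).samples
        np.testing.assert_allclose(ab, a + 2.0 * b, atol=1e-6 * np.abs(a).max())

    def test_pure_translation_only_changes_phase(self, phantom16):
        traj = kooshball_trajectory(16)
        rot_only = constant_track(traj.n_readouts, (7.0, 0.0, 0.0))
        rot_trans = constant_track(traj.n_readouts, (7.0, 0.0, 0.0), (2.3, -1.1, 0.7))
        a = simulate_motion_corrupted(phantom16, traj, rot_only).samples
        b = simulate_motion_corrupted(phantom16, traj, rot_trans).samples
        np.testing.assert_allclose(np.abs(b), np.abs(a), rtol=1e-6)

    def test_transform_count_equals_occupied_states(self, phantom16):
        traj = cartesian_trajectory(16)
        track = make_instantaneous(traj.n_readouts, 5.0, "x", (0.25, 0.5, 0.75))
        kdata = simulate_motion_corrupted(phantom16, traj, track, n_states=100)
        assert kdata.n_transforms == 2  # alternating -5/+5: two distinct poses
        assert kdata.n_transforms <= 100

    def test_track_length_mismatch_rejected(self, phantom16):
        traj = cartesian_trajectory(16)
        with pytest.raises(ValueError):
            simulate_motion_corrupted(phantom16, traj, zero_track(10))

    def test_noise_hook_defaults_off_and_is_seeded(self, phantom16):
        traj = cartesian_trajectory(16)
        clean = simulate_motion_corrupted(phantom16, traj, zero_track(traj.n_readouts))
        noisy1 = simulate_motion_corrupted(
            phantom16, traj, zero_track(traj.n_readouts), noise_snr=20.0, seed=3
        )
        noisy2 = simulate_motion_corrupted(
            phantom16, traj, zero_track(traj.n_readouts), noise_snr=20.0, seed=3
        )
        assert not np.array_equal(clean.samples, noisy1.samples)
        np.testing.assert_array_equal(noisy1.samples, noisy2.samples)


def test_h5_round_trip(tmp_path, phantom16):
    traj = cartesian_trajectory(16)
    track = make_instantaneous(traj.n_readouts, 5.0, "x")
    kdata = simulate_motion_corrupted(phantom16, traj, track)
    path = tmp_path / "kspace.h5"
    save_kspace_h5(kdata, path)
    back = load_kspace_h5(path)
    np.testing.assert_array_equal(back.samples, kdata.samples)
    np.testing.assert_array_equal(back.trajectory.coords, traj.coords)
    np.testing.assert_array_equal(back.track.rotations, track.rotations)
    assert back.n_transforms == kdata.n_transforms
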