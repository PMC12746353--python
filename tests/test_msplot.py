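"""Motion-sampling plots: value assignment, rendering, discontinuity report."""

import numpy as np
import pytest

from motionsampling import (
    build_msplot,
    cartesian_trajectory,
    discontinuity_report,
    kooshball_trajectory,
    render_msplot,
    save_msplot_h5,
    stack_of_stars_trajectory,
)
from motionsampling.motion import make_drift, make_instantaneous, make_realistic

from conftest import zero_track


class TestBuild:
    def test_constant_track_mean_reference_is_all_zero(self):
        traj = cartesian_trajectory(8)
        plot = build_msplot(traj, zero_track(traj.n_readouts), "pitch", "mean_pose")
        assert np.all(plot.values == 0.0)
        assert plot.sample_values().shape == (traj.n_samples,)

    def test_mean_reference_zeroes_readout_weighted_mean(self):
        traj = stack_of_stars_trajectory(16)
        track = make_instantaneous(traj.n_readouts, 10.0, "x", (0.1,))
        plot = build_msplot(traj, track, "pitch", "mean_pose")
        assert abs(plot.values.mean()) <= 1e-9

    def test_half_split_is_half_plane_in_ky(self):
        traj = cartesian_trajectory(16, "smooth")
        track = make_instantaneous(traj.n_readouts, 10.0, "x", (0.5,))
        plot = build_msplot(traj, track, "pitch", "absolute")
        ky = traj.meta["ky"]
        assert np.all(plot.values[ky < 0] == -10.0)
        assert np.all(plot.values[ky >= 0] == 10.0)

    def test_values_follow_spoke_angle_for_drift(self):
        traj = stack_of_stars_trajectory(16, "smooth")
        track = make_drift(traj.n_readouts, 10.0, "x")
        plot = build_msplot(traj, track, "pitch", "mean_pose")
        per_angle = {}
        for a, v in zip(traj.meta["angle"], plot.values):
            per_angle.setdefault(round(a, 9), []).append(v)
        means = [np.mean(per_angle[a]) for a in sorted(per_angle)]
        assert np.all(np.diff(means) > 0)  # monotone in spoke angle

    def test_length_mismatch_rejected(self):
        traj = cartesian_trajectory(8)
        with pytest.raises(ValueError):
            build_msplot(traj, zero_track(7), "pitch")

    def test_unknown_parameter_rejected(self):
        traj = cartesian_trajectory(8)
        with pytest.raises(ValueError):
            build_msplot(traj, zero_track(traj.n_readouts), "tilt")

    def test_rms_displacement_parameter(self):
        traj = cartesian_trajectory(8)
        track = make_instantaneous(traj.n_readouts, 10.0, "x", (0.5,))
        plot = build_msplot(traj, track, "rms_displacement", "absolute")
        assert np.all(plot.values >= 0.0)
        assert plot.values.max() > 0.0


class TestDiscontinuityReport:
    def test_constant_track_empty_report(self):
        traj = cartesian_trajectory(16)
        plot = build_msplot(traj, zero_track(traj.n_readouts), "pitch", "mean_pose")
        assert discontinuity_report(plot) == []

    def test_half_split_single_center_critical_ky_jump(self):
        traj = cartesian_trajectory(64, "smooth")
        track = make_instantaneous(traj.n_readouts, 10.0, "x", (0.5,))
        rep = discontinuity_report(build_msplot(traj, track, "pitch", "absolute"))
        assert len(rep) == 1
        entry = rep[0]
        assert entry["axis"] == "ky"
        assert entry["jump"] == pytest.approx(20.0)
        assert abs(entry["location"]) <= 0.5
        assert entry["center_critical"]

    def test_edge_split_not_center_critical(self):
        n = 64
        traj = cartesian_trajectory(n, "smooth")
        track = make_instantaneous(traj.n_readouts, 10.0, "x", (0.1,))
        rep = discontinuity_report(build_msplot(traj, track, "pitch", "absolute"))
        ky_entries = [e for e in rep if e["axis"] == "ky"]
        assert len(ky_entries) == 1
        assert ky_entries[0]["location"] == pytest.approx(-0.4 * n, abs=1.0)
        assert not ky_entries[0]["center_critical"]

    def test_drift_smooth_stack_of_stars_max_jump_at_wrap(self):
        traj = stack_of_stars_trajectory(32, "smooth")
        track = make_drift(traj.n_readouts, 10.0, "x")
        rep = discontinuity_report(build_msplot(traj, track, "pitch", "mean_pose"))
        assert len(rep) == 1
        entry = rep[0]
        assert entry["axis"] == "angle"
        # maximal pose jump sits at the 0/180 spoke boundary, magnitude ~ full range
        assert entry["location"] == pytest.approx(180.0, abs=2.0)
        assert entry["jump"] == pytest.approx(20.0, abs=1.0)
        assert entry["center_critical"]

    def test_kooshball_report_runs(self):
        traj = kooshball_trajectory(16, "smooth")
        track = make_instantaneous(traj.n_readouts, 10.0, "x", (0.5,))
        rep = discontinuity_report(build_msplot(traj, track, "pitch", "absolute"))
        assert all(e["jump"] > 0 for e in rep)


def test_drift_under_random_ordering_is_noiselike():
    # non-smooth Cartesian turns a drift ramp into a spatially uncorrelated
    # value field on the phase-encode plane
    n = 64
    traj = cartesian_trajectory(n, "non_smooth", seed=0)
    track = make_drift(traj.n_readouts, 10.0, "x")
    plot = build_msplot(traj, track, "pitch", "mean_pose")
    c = n // 2
    grid = np.zeros((n, n))
    grid[
        np.round(traj.coords[:, 0, 1]).astype(int) + c,
        np.round(traj.coords[:, 0, 2]).astype(int) + c,
    ] = plot.values
    v = grid - grid.mean()
    lag1 = np.mean(v[:-1, :] * v[1:, :]) / np.mean(v * v)
    assert abs(lag1) <= 0.1


def test_render_and_h5_export(tmp_path):
    traj = stack_of_stars_trajectory(8)
    track = make_realistic(traj.n_readouts, seed=0)
    plot = build_msplot(traj, track, "pitch", "mean_pose")
    png = tmp_path / "msplot.png"
    render_msplot(plot, png)
    assert png.exists() and png.stat().st_size > 0
    h5 = tmp_path / "msplot.h5"
    save_msplot_h5(plot, h5)
    import h5py

    with h5py.File(h5) as f:
        assert f["coordinates"].shape == (traj.n_samples, 3)
        assert f.attrs["parameter"] == "pitch"
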