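"""Preset experiment grids and end-to-end orchestration.

The core study design crosses three trajectories (Cartesian, stack-of-stars,
kooshball) with two view orderings (smooth, non-smooth) and three motion
patterns (instantaneous, drift, realistic) -- 18 combinations -- plus presets
that move a pose discontinuity through k-space, rotate about different axes,
and sweep motion magnitude.  ``run_experiment`` executes the full pipeline
(phantom -> trajectory -> motion -> simulation -> reconstruction ->
motion-sampling plot) and writes volumes, plots, metrics and a provenance
record sufficient to re-run the experiment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .motion import (
    MotionTrack,
    load_track_tsv,
    make_drift,
    make_instantaneous,
    make_realistic,
    resample_track,
)
from .msplot import build_msplot, discontinuity_report, render_msplot
from .phantom import make_shepp_logan_3d
from .recon import nrmse, reconstruct
from .simulate import DEFAULT_N_STATES, simulate_motion_corrupted
from .trajectory import make_trajectory

TRAJECTORIES = ("cartesian", "stack_of_stars", "kooshball")
ORDERINGS = ("smooth", "non_smooth")
MOTIONS = ("instantaneous", "drift", "realistic")

#: Motion magnitudes studied: small, medium, large (degrees, +/-).
MAGNITUDES_DEG = (1.5, 5.0, 10.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully specified simulation experiment (trajectory x ordering x motion)."""

    name: str
    n: int = 130
    trajectory: str = "cartesian"
    ordering: str = "smooth"
    motion: str = "instantaneous"
    amplitude_deg: float = 10.0
    axis: str = "x"
    seed: int = 0
    n_states: int = DEFAULT_N_STATES
    switch_fractions: tuple[float, ...] = (0.5,)
    start_sign: int = -1
    track_file: str | None = None
    msplot_parameter: str = "pitch"
    msplot_reference: str = "mean_pose"
    flags: tuple[str, ...] = ()


def build_track(config: ExperimentConfig, n_readouts: int) -> MotionTrack:
    """Construct the motion track an experiment config describes."""
    if config.track_file is not None:
        return resample_track(load_track_tsv(config.track_file), n_readouts)
    if config.motion == "instantaneous":
        return make_instantaneous(
            n_readouts,
            config.amplitude_deg,
            config.axis,
            config.switch_fractions,
            config.start_sign,
        )
    if config.motion == "drift":
        return make_drift(n_readouts, config.amplitude_deg, config.axis)
    if config.motion == "realistic":
        return make_realistic(n_readouts, seed=config.seed)
    raise ValueError(f"unknown motion pattern {config.motion!r}")


_AXIS_PARAM = {"x": "pitch", "y": "roll", "z": "yaw"}


def grid_18(
    n: int = 130, amplitude_deg: float = 10.0, axis: str = "x", seed: int = 0
) -> list[ExperimentConfig]:
    """The 18 motion-sampling combinations: 3 trajectories x 2 orderings x 3
    motion patterns, each fully specified and runnable end-to-end."""
    if n < 16:
        raise ValueError("grid_18 needs n >= 16")
    configs = []
    for traj in TRAJECTORIES:
        for ordering in ORDERINGS:
            for motion in MOTIONS:
                configs.append(
                    ExperimentConfig(
                        name=f"{traj}_{ordering}_{motion}",
                        n=n,
                        trajectory=traj,
                        ordering=ordering,
                        motion=motion,
                        amplitude_deg=amplitude_deg,
                        axis=axis,
                        seed=seed,
                        msplot_parameter=_AXIS_PARAM[axis],
                    )
                )
    return configs


def shift_experiment(n: int = 130) -> list[ExperimentConfig]:
    """Discontinuity-shift presets: the negative pose state starts at 0%, 25%
    or 40% of the scan and occupies 10% or 50% of it; smooth ordering, +/-10
    deg pitch, all three trajectories (18 configs)."""
    if n < 16:
        raise ValueError("shift_experiment needs n >= 16")
    configs = []
    for traj in TRAJECTORIES:
        for split in (0.10, 0.50):
            for start in (0.0, 0.25, 0.40):
                if start == 0.0:
                    switches, start_sign = (split,), -1
                else:
                    switches, start_sign = (start, start + split), +1
                configs.append(
                    ExperimentConfig(
                        name=f"{traj}_shift{int(start * 100):02d}_split{int(split * 100):02d}",
                        n=n,
                        trajectory=traj,
                        ordering="smooth",
                        motion="instantaneous",
                        amplitude_deg=10.0,
                        axis="x",
                        switch_fractions=switches,
                        start_sign=start_sign,
                    )
                )
    return configs


def direction_experiment(n: int = 130) -> list[ExperimentConfig]:
    """Motion-direction presets: drift and instantaneous motion about each of
    the x, y, z axes with the sampling unchanged (6 configs per trajectory).

    Stack-of-stars with z-axis rotation is flagged as the combination that has
    no in-vivo counterpart (through-z rotations are not performed in vivo).
    """
    if n < 16:
        raise ValueError("direction_experiment needs n >= 16")
    configs = []
    for traj in TRAJECTORIES:
        for motion in ("drift", "instantaneous"):
            for axis in ("x", "y", "z"):
                flags = ()
                if traj == "stack_of_stars" and axis == "z":
                    flags = ("no_in_vivo_counterpart",)
                configs.append(
                    ExperimentConfig(
                        name=f"{traj}_{motion}_axis_{axis}",
                        n=n,
                        trajectory=traj,
                        ordering="smooth",
                        motion=motion,
                        amplitude_deg=10.0,
                        axis=axis,
                        msplot_parameter=_AXIS_PARAM[axis],
                        flags=flags,
                    )
                )
    return configs


def magnitude_experiment(n: int = 130, ordering: str = "non_smooth") -> list[ExperimentConfig]:
    """Magnitude sweep: drift and instantaneous pitch motion at small, medium
    and large amplitude (+/-1.5, +/-5, +/-10 degrees)."""
    configs = []
    for traj in TRAJECTORIES:
        for motion in ("drift", "instantaneous"):
            for amp in MAGNITUDES_DEG:
                configs.append(
                    ExperimentConfig(
                        name=f"{traj}_{motion}_amp{amp:g}",
                        n=n,
                        trajectory=traj,
                        ordering=ordering,
                        motion=motion,
                        amplitude_deg=amp,
                        axis="x",
                    )
                )
    return configs


def reference_pose_track(track: MotionTrack, n_states: int = DEFAULT_N_STATES) -> MotionTrack:
    """Constant track at the pose against which artifact severity is judged.

    A motion-corrupted image is mostly an image of the phantom in its
    *dominant* pose; measuring error against the identity pose would conflate
    artifact energy with the global pose offset.  The reference is therefore
    the discretized state occupying the largest share of readouts when that
    share is at least half the scan, and the mean pose otherwise (drift,
    realistic motion).
    """
    from .motion import discretize_states, state_labels

    d = discretize_states(track, n_states)
    labels = state_labels(d)
    counts = np.bincount(labels)
    top = int(np.argmax(counts))
    n = track.n_readouts
    if counts[top] >= 0.5 * n:
        i = int(np.flatnonzero(labels == top)[0])
        rot = np.tile(d.rotations[i], (n, 1))
        trans = np.tile(d.translations[i], (n, 1))
    else:
        rot = np.tile(track.rotations.mean(axis=0), (n, 1))
        trans = np.tile(track.translations.mean(axis=0), (n, 1))
    return MotionTrack(rot, trans, center_of_rotation=track.center_of_rotation)


def run_experiment(config: ExperimentConfig, outdir=None, render: bool = True) -> dict:
    """Execute the full pipeline for one experiment config.

    Returns ``{"volume", "reference", "msplot", "metrics", "kdata"}``; when
    ``outdir`` is given also writes ``volume.nii.gz``, ``msplot.png``,
    ``metrics.csv`` and ``provenance.json`` there.  Errors are re-raised with
    the pipeline stage prepended.
    """
    stage = "phantom"
    try:
        phantom = make_shepp_logan_3d(config.n)
        stage = "trajectory"
        traj = make_trajectory(config.trajectory, config.n, config.ordering, config.seed)
        stage = "motion"
        track = build_track(config, traj.n_readouts)
        stage = "simulate"
        kdata = simulate_motion_corrupted(phantom, traj, track, n_states=config.n_states)
        stage = "recon"
        vol = reconstruct(kdata)
        ref_track = reference_pose_track(track, config.n_states)
        ref_kdata = simulate_motion_corrupted(phantom, traj, ref_track, n_states=1)
        ref_vol = reconstruct(ref_kdata)
        stage = "msplot"
        plot = build_msplot(traj, track, config.msplot_parameter, config.msplot_reference)
        report = discontinuity_report(plot)
        stage = "metrics"
        metrics = {
            "nrmse_vs_motion_free": nrmse(vol, ref_vol),
            "nrmse_motion_free_vs_phantom": nrmse(ref_vol, phantom),
            "n_transforms": kdata.n_transforms,
        }
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    result = {
        "volume": vol,
        "reference": ref_vol,
        "msplot": plot,
        "metrics": metrics,
        "kdata": kdata,
        "discontinuities": report,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import save_volume_nifti

        save_volume_nifti(np.abs(vol), outdir / "volume.nii.gz")
        save_volume_nifti(np.abs(ref_vol), outdir / "reference.nii.gz")
        if render:
            render_msplot(plot, outdir / "msplot.png")
        import pandas as pd

        pd.DataFrame([metrics]).to_csv(outdir / "metrics.csv", index=False)
        provenance = {
            "config": asdict(config),
            "package_version": __version__,
            "discontinuities": report,
        }
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return result


def run_from_provenance(path, outdir=None) -> dict:
    """Re-run an experiment from its provenance.json record."""
    rec = json.loads(Path(path).read_text())
    cfg = rec["config"]
    cfg["switch_fractions"] = tuple(cfg["switch_fractions"])
    cfg["flags"] = tuple(cfg.get("flags", ()))
    return run_experiment(ExperimentConfig(**cfg), outdir=outdir)
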