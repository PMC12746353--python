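# Methods

This note documents the models, conventions and numerical choices behind
`motionsampling`, and states plainly what the simulations do and do not show.

## Coordinate and pose conventions

Array axes (0, 1, 2) are the physical x (left-right), y (anterior-posterior)
and z (superior-inferior) directions.  The physical origin is voxel index
`n // 2` on each axis (the FFT center convention); normalized phantom
coordinates are `(index - n//2) / (n/2)`.  k-space coordinates are in
cycles/FOV, so the Cartesian grid occupies the integers `[-n/2, n/2 - 1]`.

A rigid pose is (pitch, roll, yaw) in degrees about the fixed scanner x, y, z
axes plus a translation in voxels.  Rotations are extrinsic and compose as
`R = Rz(yaw) @ Ry(roll) @ Rx(pitch)` with the right-hand rule.  The
composition order is a convention the literature rarely states; fixing it
(and the one-pose-per-readout rule) is what makes runs reproducible.  The
center of rotation defaults to the grid center; an off-center rotation point
is folded into an equivalent translation `t_eff = (I - R)(c_rot - c_grid) + t`.

## Phantom

The head phantom is the ten-ellipsoid 3D Shepp-Logan object (the classical
geometry with the "modified" high-contrast intensities; the full table is in
`phantom.SHEPP_LOGAN_3D` and exportable as CSV).  Voxels are the exact
indicator-function sum at voxel centers, so edges are sharp (one-voxel
transitions).  Different published intensity variants change image contrast
but not artifact structure, so no attempt is made to match any particular
figure pixel-for-pixel.

Sharp binary edges have a consequence worth stating: interpolation and
gridding errors concentrate in a one-voxel shell around each edge, which
dominates several whole-volume NRMSE numbers below.  The cubic-spline
pose/inverse-pose round trip measures 0.12 NRMSE at n=130 and 0.20 at n=64 —
this is edge resampling error, not pose drift (total intensity is conserved
to 1e-6 under rotation, and the composition of rotations agrees with the
single rotation to 0.11 NRMSE at n=64).  These measured values are frozen as
regression bounds (0.15 and 0.25).

## Trajectories

All three trajectories are generated at the theoretical Nyquist limit with a
ceiling convention, which reproduces the standard counts (205 in-plane spokes
and 26 547 kooshball spokes at n=130; 25 600 / 40 320 / 40 213 readouts at
n=160):

* **Cartesian** — one full kx line per (ky, kz); smooth ordering is the
  nested loop with ky slow (outer, low to high) and kz fast; non-smooth is a
  uniform shuffle of the same set, reproducible from a seed.
* **Stack-of-stars** — `ceil(n*pi/2)` full in-plane spokes, kz Cartesian and
  looped low-to-high inside each spoke angle; smooth ordering sweeps
  uniformly spaced angles over [0, 180), non-smooth increments by the level-3
  tiny golden angle `180/(tau + 2) = 49.75` degrees mod 180.
* **Kooshball** — `ceil(n^2*pi/2)` full spokes on the upper half-sphere.
  Smooth ordering follows an equal-area spiral (z linear from the +z pole to
  the equator, azimuth incremented by `3.6 / sqrt(2M (1 - z^2))` for uniform
  arc length); the sweep direction decides which pole anchors the ordering
  and the orientation — not the severity class — of ordering-dependent
  artifacts.  Non-smooth ordering uses the two multidimensional golden means
  (1/psi^2, 1/psi with psi the real root of x^3 = x^2 + 1) as increments for
  (z, azimuth).  A finer-grained "tiny" variant of the golden-means pair
  exists in the literature; the level-1 constants are used here, which
  preserves the quasi-random half-sphere coverage that drives the artifact
  structure.

Full spokes are extended by sqrt(2) (in-plane) and sqrt(3) so their endpoints
reach the corners of the Cartesian grid.  Samples are uniformly spaced along
each spoke at ~1 cycle/FOV, with the count rounded up to odd so that **every
spoke contains an exact DC sample**: with all innermost samples half a
spacing off center the density compensation develops a near-DC pathology
(measured in a 2D side experiment: 0.28 vs 0.089 NRMSE for a smooth test
object).

## Motion tracks

One pose per readout (motion during the few-ms signal readout is ignored).
Generators:

* **Instantaneous** — piecewise constant, alternating between -A and +A at
  switch fractions; boundaries snap to whole readouts (`floor(f * N)`).
* **Drift** — pitch (or roll/yaw) linear from -A to +A over the scan.
* **Realistic (synthetic)** — emulates unsedated pediatric patients: the
  head rests at a pose, makes Poisson-timed instantaneous jumps to new rest
  poses (jump scale calibrated so the expected pitch peak-to-peak matches the
  profile target of 16 degrees), and wanders in slow random-walk drift
  episodes covering ~15% of readouts; roll/yaw scaled to 0.35 of pitch;
  translations coupled to rotation through a 15-voxel head-pivot lever arm.
  Everything is reproducible from a seed.  A readout counts as "in motion"
  when any rotation parameter changes by more than 0.02 degrees per TR — a
  deliberate operationalization of a speed threshold, since tracking studies
  rarely state theirs.
* **External tracks** — TSV files (readout, rx, ry, rz, tx, ty, tz; degrees
  and mm) are stretched to the scan's readout count by nearest-neighbor
  interpolation in normalized time, which introduces no new pose values.

What the synthetic generator does **not** emulate: correlated physiological
micro-motion, tracking noise, or the exact temporal statistics of any real
patient cohort.  Tests passing on it show the pipeline handles realistic
magnitudes and timing structure, not that it reproduces any specific
recording.

Tracks are discretized to 100 motion frames (contiguous equal-time bins,
bin-mean representative) before simulation; the phantom is transformed once
per occupied frame, never more than 100 times per scan.

The single-number pose summary `rms_displacement` is the closed form
`sqrt(R^2/5 * trace(A'A) + t't)` (A = rotation minus identity): the RMS
displacement of points uniform in a solid sphere, 64 mm radius by default.

## Forward model and NUFFT

The forward model samples `F(k) = sum_r x(r) exp(-2 pi i k.r / n)`.  On
integer Cartesian coordinates this is gathered from the centered FFT
(exact); elsewhere a type-2 gridding NUFFT is used: deapodize, zero-pad to a
2x oversampled grid, FFT, interpolate with a width-8 Kaiser-Bessel kernel
(Beatty shape parameter, 32k-entry lookup table).  Against a brute-force DFT
the pointwise relative error is ~5e-7.  Sample positions wrap modulo the
oversampled grid, matching the n-periodicity of a discrete image's spectrum,
so the extended spoke tips are handled consistently.  Translations multiply
the sampled spectrum by an exact unit-magnitude linear phase, so pure
translations never touch the interpolator.  No noise is added by default; a
seeded complex-white-noise hook with configurable SNR exists.

## Reconstruction and its floor

Cartesian data are inverted with a single inverse FFT (round trip exact to
1e-6 and beyond).  Radial data use density-compensated adjoint gridding: an
analytic ramp (|k| in-plane for stack-of-stars, |k|^2 for kooshball) in
grid-cell units, the DC sample weighted by the innermost annulus volume, and
samples outside the Cartesian Nyquist cube excluded (their contributions
would wrap onto aliased grid cells and over-weight them).

The adjoint-plus-ramp reconstruction has an honest, object-dependent error
floor: for the sharp Shepp-Logan phantom filling ~0.92 of the FOV, the
motion-free NRMSE versus the phantom measures **~0.32 for stack-of-stars and
~0.60 for kooshball** (stable across n=32 and n=64; frozen as regression
bounds 0.36 / 0.65).  The cause is structural, not a tuning matter: the
spectrum of a near-full-FOV object decorrelates within about one grid cell
(correlation ~ sinc(0.92 d) ≈ 0.09 one cell away), so no local kernel or
density-compensation scheme can recover individual grid cells from off-grid
samples at exactly-Nyquist spoke counts; a global least-squares solve can
(verified on a dense small instance, error ~1e-15), but iterative
reconstruction is deliberately out of scope for this simulator.  Pipe-Menon
iterative weights, exact annulus volumes, per-cell post-compensation,
anti-aliased phantom rasterization and FOV-clipping variants were all
evaluated and none move the floor materially.  The practical consequence is
benign for the package's purpose: **artifact severity is always measured
against the motion-free reconstruction of the same trajectory**, so the
gridding floor cancels out of every severity comparison.

Severity is `NRMSE = ||x - ref||_2 / ||ref||_2` over magnitude images, with
the reference reconstructed at the track's *dominant pose* — the discretized
state holding at least half the readouts, else the mean pose.  Without this
convention a 90/10 pose split is swamped by the global 10-degree offset
(~0.48 NRMSE regardless of where the discontinuity sits) and the
location-of-discontinuity effect is invisible.

## Motion-sampling plots

Every sample of readout i carries the chosen pose parameter of pose i
(pitch/roll/yaw in degrees or RMS displacement in mm).  The default
reference subtracts the readout-weighted mean pose, zeroing the mean of the
plotted values (for angle parameters); absolute values are available when
comparing temporal shifts.  Renderings show a 3D scatter plus the three
orthogonal projections with a symmetric diverging color scale (+/- max
|value|); clouds above 2e5 points are subsampled for display only (fixed
seed) — the data object is never subsampled.  Half-sphere radial
trajectories are plotted as acquired; conjugate-symmetric mirror samples are
not added.

The discontinuity report scans for the largest pose jump between spatially
adjacent samples: per phase-encode axis between neighboring integer
coordinates (Cartesian), and between angle-sorted adjacent spokes including
the 0/180 wrap (radial; kooshball spokes are binned by azimuth, 64 bins).
The distance to the k-space center is taken at the closest jumping point of
the boundary, and jumps closer than n/8 are flagged center-critical; radial
discontinuities run along full spokes through DC and are always flagged.
The report flags discontinuities only — it does not classify artifact types,
which remains an expert judgement.

## Experiment presets and sizes

`grid_18` builds the 3 trajectories x 2 orderings x 3 motion patterns cross
product; `shift_experiment` moves a 10%/90% or 50%/50% instantaneous +/-10
degree pitch split to start at 0%, 25% or 40% of the scan (smooth ordering);
`direction_experiment` applies drift and instantaneous rotations about each
axis with the sampling unchanged (stack-of-stars with z-rotation is flagged
as having no in-vivo counterpart); `magnitude_experiment` sweeps +/-1.5, 5
and 10 degrees.  `run_experiment` writes NIfTI volumes, plot PNGs, a metrics
CSV and a provenance JSON from which any run can be repeated bit-identically.

The default simulation matrix is 130 (overridable); the test suite and the
acceptance script run at 16-64 cubes, which keeps the full suite at a few
minutes on one CPU while preserving every qualitative effect studied.
Measured behaviors at n=64: the magnitude sweep is strictly monotone (0.14 /
0.30 / 0.37 NRMSE for drift + non-smooth Cartesian); corrupting the first
10% of a smooth Cartesian scan is strictly milder than a 40%-shifted
discontinuity (0.10 vs 0.18).  For kooshball the severity across the three
shift positions spans 0.15-0.24: equal-solid-angle wedges do not carry equal
inconsistency energy for a pitch flip (the difference spectrum is small near
the rotation axis), and mid-scan windows create two state boundaries instead
of one, so "severity is roughly constant" holds only loosely (~70% relative
spread) under this metric.

## Known limitations

Secondary motion effects (B0 changes, coil sensitivity motion, spin history,
out-of-slab effects), multi-channel reception, parallel imaging and
compressed sensing, readout-internal motion, and motion-corrected or
iterative reconstruction are all out of scope.  NRMSE floors and regression
bounds quoted above are properties of this phantom and reconstruction class;
smoother or smaller objects reconstruct with correspondingly lower floors.
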