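# Methods

`neurokym` quantifies 4D (3D + time) fluorescence time-lapse recordings of
radially migrating neurons — cerebellar granule neurons moving along glial
fibers being the motivating system — together with the organelle-track and
photobleaching assays that accompany such recordings. This note describes
the models and procedures the package implements, the choices made where
the design was genuinely open, and what the synthetic-data generator does
and does not emulate.

## Coordinate conventions

Image stacks are ordered `(t, c, z, y, x)`. Voxel indices are 0-based; the
physical coordinate of a voxel is `index × voxel size` at the voxel centre,
and all physical points in the API are `(x, y, z)` triples in micrometres.
Ranges and kymograph bins are half-open. One stated convention everywhere
prevents off-by-one drift between modules.

## Seeded segmentation with exclusion walls

A cell is segmented per frame as the 6-connected component (in-plane
4-neighbourhood plus the two z-neighbours) of `{I ≥ θ}` containing a soma
seed voxel. The threshold `θ` is per cell and constant over the sequence;
an Otsu initializer is available but never applied implicitly, because a
silent threshold change mid-sequence would make kymograph columns
incomparable. Seeds for later frames are propagated from the previous
mask's intensity-weighted centroid; if the centroid of an elongated cell
falls below threshold (it can land between soma and process), the previous
seed is reused, and a frame whose seed fails entirely is flagged rather
than silently returned empty.

"Walls" are user-supplied polylines in x-y pixel coordinates that are
rasterized 8-connected (Bresenham), extruded through every z section, and
set to zero intensity before thresholding. 6-connectivity for the
segmentation is a deliberate pairing: a one-pixel-thick 8-connected curve
is a separator for 4-connected paths in the plane, so its extrusion blocks
every 6-connected 3D path. This makes a hand-drawn wall a *guaranteed*
fence against bleeding into an adjacent cell, which the tests verify
against an independent breadth-first path search on randomized two-blob
fixtures.

## Adaptive volumetric kymographs

The migration axis is the unit vector from the soma centroid to the tip of
the leading process in the first frame, anchored in the laboratory frame
for the whole sequence (a per-frame re-anchored axis is available behind a
flag but is never the default, because a moving origin folds soma motion
into every overlay). Each masked voxel centre is projected onto the axis,
`s = (p − origin) · d`, and assigned to the half-open bin
`[iΔ, (i+1)Δ)` with `Δ` equal to the x-y pixel size — cross-sections one
pixel apart. Boundary assignment by `floor(s/Δ)` is the package's choice;
any rule that partitions the line works, but it must be half-open so no
voxel is counted twice.

A kymograph column is the sum or the max of its cross-section intensities;
both statistics are first-class. With the sum statistic, column totals
equal the frame's total masked fluorescence — integer inputs are
accumulated in 64-bit integers so this conservation is exact, and the test
suite asserts it against a brute-force per-voxel loop.

Overlays: the soma is located as the largest 6-connected component of the
thresholded nucleus channel inside the mask (per-frame Otsu by default),
dilated along the axis by a 1 μm margin; `s_min/s_max` are its projected
extremes and `s_center` its intensity-weighted projected centroid. For
nucleus-free data a width-profile fallback takes the soma as the
contiguous run of bins whose cross-section area is ≥ 50 % of the frame
maximum. Tracked organelles are projected onto the same axis.

## Cylindrical local concentration

The local concentration of a marker (e.g. F-actin) around a tracked object
is the mean masked intensity inside a cylinder: a disk of radius 1, 2 or
4 μm around the object's x-y position, extruded through all z, intersected
with the segmented cell. The cylinder axis is taken parallel to z: with
3–4× coarser sampling and a 2–3× wider point-spread function axially, an
in-plane disk is the scale-probe that matches what the instrument actually
resolves, and it makes the three radii directly comparable. The whole-cell
mean over the same mask is reported as the baseline. Empty intersections
are flagged explicitly, never reported as zero.

## Compartment signal fractions

Each frame's cell is partitioned along the axis by the soma interval
`[s_min, s_max]`: leading process `s > s_max`, trailing process
`s < s_min`, soma the closed interval (ties count as soma). Fractions are
intensity-weighted — the fraction of the channel's masked fluorescence in
each compartment — normalized per frame, and sum to 1 whenever the frame
carries signal; zero-signal frames are flagged with undefined fractions.

## Velocity statistics

A track's average velocity is the mean of per-step speeds `|Δp|/Δt` over
consecutive present frames; gaps contribute no step. The alternative (net
displacement over total time) underestimates saltatory motion and does not
match per-timepoint kinetic plots, so step-mean is the estimator
throughout. Inclusion rules mirror the assay design: a track must be
visible for ≥ 5 consecutive frames, and a neuron counts as migrating when
its net first-to-last displacement strictly exceeds two cell-body lengths
(default: the frame-0 soma extent along the axis).

Drug-addition experiments split each track at the addition time (default
24 min) and discard an exclusion window (default 26–32 min, covering
focus loss during pipetting); pre, window and post partition the frames
exactly. Group comparisons use Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom — group variances in this kind of
data differ severalfold, so the pooled-variance test would be wrong more
often than not. Degenerate inputs (two constant, equal groups) are
reported as t = 0, p = 1 with a flag. The basal-motility assay summarises
5-minute, 15-second-interval blocks (pre-treatment, then every 10 minutes)
as one velocity group per block; empty blocks are omitted, never zeroed.

## FRAP recovery model

Post-bleach traces are fitted to a single-exponential recovery with a
fixed bleach floor,

    I(t) = I_post + (I_plateau − I_post)(1 − e^{−kt}),

with `I_post` pinned to the first post-bleach sample and
`(I_plateau, k)` free. Then `t_1/2 = ln 2 / k` and the mobile fraction is
`(I_plateau − I_post)/(I_pre − I_post)`, with `I_pre` the mean of the
pre-bleach samples. This is the minimal model that yields both reported
quantities; diffusion-reaction models and bleach-geometry corrections are
out of scope. The rate is initialized from a log-linear fit of the
normalized recovery deficit, negative rates are excluded by bound, and a
non-increasing trace is reported as non-converged with a diagnostic rather
than fitted. The fit is invariant to affine intensity rescaling, and in
the noiseless limit recovers `(k, mobile fraction)` exactly over the
tested grid `k ∈ [0.05, 1] s⁻¹`, mf ∈ [0.2, 1].

## The synthetic scene generator

The generator exists so every downstream stage is testable against known
truth without external recordings. It emulates, on a default grid of 13
z-sections spanning 10 μm with 0.25 μm x-y pixels and 2-minute frames:

* **Cell geometry.** A soft sphere (soma, radius 2.5 μm) with a tapered
  leading process (15 μm) and a shorter trailing process (6 μm), rendered
  as a sigmoid-softened signed-distance solid evaluated at voxel centres.
  The cell translates rigidly along +x, so total cell-channel intensity is
  conserved across frames to grid precision.
* **Two-stroke kinematics.** A square-wave phase model: within each cycle
  (default 20 min) the organelle advances during the first half and the
  nucleus catches up at twice the mean speed during the second, advancing
  exactly `v × period` per cycle. The organelle is the constant drift
  `v·t` plus a triangular lead (default amplitude 5 μm), so it never trails
  the nucleus. Lead amplitude and period are not constrained by published
  measurements; the defaults are plausible for this cell type and are
  stated here once. Setting the lead amplitude to zero selects a
  constant-speed degenerate mode used for estimator-recovery tests. An
  optional drug time scales all subsequent step sizes by a constant
  factor.
* **Channels.** Nucleus (soft sphere), organelle punctum (Gaussian,
  composed analytically with the PSF), actin (cell fill plus a proximal
  leading-process hotspot, by default fixed in the cell frame just ahead
  of the soma; optionally centred on the organelle), and adhesion puncta
  fixed in the laboratory frame that the soma slides past.
* **Noise.** Poisson on the signal, then additive Gaussian; both optional
  and applied after geometry, under a single seeded generator —
  identical config and seed give byte-identical stacks, and ground truth
  is independent of the noise seed.

Synthetic organelle *tracks* (for velocity recovery) take a fixed per-step
speed with either a fixed random heading (migration) or per-step random
headings (basal motility), plus Gaussian localization noise on x and y.
z is carried noise-free: manual tracking on serial optical sections
localizes in-plane, while axial position is quantized to the 0.83 μm
section spacing, for which a Gaussian per-axis model would be wrong. Note
that localization noise still inflates mean step speeds (≈ +1 % at the
2-minute assay's 1.1 μm steps, ≈ +8 % at the 15-second assay's 0.2 μm
steps with 0.05 μm noise); the recovery tests accept the estimate within
10 % of the generating speed, which contains this bias rather than
correcting it, since the estimator under test is the plain step mean.

What the generator does **not** emulate: optics beyond a Gaussian PSF,
glial-fiber substrate, crowded multi-cell fields (beyond two-blob wall
fixtures), photobleaching of the imaging channels, focus drift, or
anisotropic organelle shapes. Passing tests therefore demonstrate that the
estimators recover known truth under the assumed statistical structure —
not that segmentation or tracking would survive arbitrary real-data
pathology.

## Numerical choices and degenerate inputs

* Kymograph accumulation: int64 for integer inputs (exact), float64
  otherwise.
* Empty kymograph bins are 0 with an explicit emptiness flag (relevant for
  the max statistic).
* Threshold ≤ 0 on an all-positive volume warns (the "component" would be
  the whole frame).
* Wall vertices are rounded to the pixel grid before rasterization;
  vertices outside the grid are a hard geometry error.
* Degenerate migration axes (tip = centroid) are a hard error, not a
  default direction.
* Mobile fractions outside [0, 1] are clipped and flagged.
* Seeds: every stochastic routine takes either a seed or a NumPy
  `Generator`; nothing reads global random state.

## Problem sizes

Default test scenes are 13 frames of 13 × 48 × 160 voxels (4 channels),
which render in under a second; the full test suite runs in ~10 s and the
benchmark script (`scripts/acceptance.py`) in a few seconds. These sizes
were chosen to keep the feedback loop tight while still exercising
anisotropic voxels, multi-micron geometry and realistic track counts.
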