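# Methods

## Readouts and their definitions

The package reproduces the two standard readouts of a tumoroid/T-cell
co-culture cytotoxicity assay, computed per z-plane and aggregated per
z-stack:

**Killing fraction.** In each z-section, nuclei, PI objects and T-cells
are segmented independently. A PI object is related to the nucleus whose
footprint contains the PI centroid; PI on background is discarded. A
nucleus is dead iff at least one PI object is assigned to it (idempotent —
multiple PI fragments mark it dead once). The whole-tumoroid killing
fraction at a timepoint is Σ dead / Σ nuclei over all planes. Planes with
no nuclei contribute nothing; a stack with no nuclei at all reports 0 with
an explicit zero-denominator flag rather than NaN. Normalization to a
positive control is `100 · fraction / control_fraction` and may exceed
100%.

**In-tumoroid T-cell count.** The tumoroid boundary is built per plane
from the nuclei channel: union of nucleus footprints → morphological
closing (default disk radius 20 µm) → hole filling → per-plane convex
hull. The hull step is a deliberate design choice: at desk-scale nucleus
density (see below) a closing alone leaves the cross-section porous, while
the tumoroid is convex to an excellent approximation, so the hull of the
detected footprints is the natural boundary estimator. All three steps are
extensive and monotone, so adding a nucleus can never shrink the mask. A
T-cell is inside iff its centroid pixel is mask-true (boundary pixels count
as inside); inside + outside always equals the number of detections. The
reported count is the sum over all z-sections, which counts a cell once per
plane it appears in — with a 10 µm z-step a cell can span two sections, a
known inflation kept deliberately because it matches the assay's stated
counting rule.

Coordinates are pixel-center physical units: the center of voxel
(z, y, x) is at ((x+0.5)·px, (y+0.5)·px, (z+0.5)·z_step) µm; all public
APIs exchange µm.

## Segmentation

Per plane: Gaussian smoothing (default σ 2 µm) → global threshold →
optional distance-transform watershed split of touching objects → area
filter (default 10–10,000 µm²) → deterministic raster-order relabeling.
The pipeline derives one global threshold per channel from the whole stack
(Otsu on a frame subsample, floored at median + 5 robust SD of the channel)
rather than per-plane Otsu: sparse planes — z-sections beyond the tumoroid,
or a PI channel with no killing — would otherwise be thresholded inside
their noise floor. A fixed numeric threshold can be configured instead.
Constant (information-free) planes always yield zero objects.

## 3D tracking

Detection thresholds the T-cell channel volume per timepoint, labels 3D
connected components on the anisotropic voxel grid and keeps components
with physical volume strictly inside the single-cell gate
(280, 10,000) µm³, reducing each to an intensity-weighted center of mass.
Linking solves, per consecutive frame pair, a one-to-one assignment by the
Hungarian algorithm on a padded square cost matrix: pair cost is Euclidean
distance, pairs beyond the displacement gate (default 30 µm/frame) are
forbidden, and the cost of leaving a detection unmatched equals the gate —
so the solution maximizes the number of gated matches and, among those,
minimizes total distance. There is no motion model and no gap closing: a
detection missing for one frame splits its track, and fragments are removed
by the minimum-duration filter (default 10 h, matching the data requirement
of the 10 h diffusive-fraction statistic).

## Motility model

Per-trajectory MSD uses the time-averaged estimator over all ordered pairs
(overlapping windows) at integer multiples of the frame interval. The model

    msd(t_lag) = 4 D t_lag + v² t_lag²

is fitted by unweighted least squares in the parameters (a = 4D, b = v²)
with nonnegativity enforced (NNLS); optional pair-count weighting is
available but off by default. The per-cell fit range defaults to lags
1–25 h, capped at half the track duration to avoid the poorly averaged
high-lag tail; population MSD curves extend to 30 h. The diffusive
fraction

    f_D = 1 / (1 + v² t_D / (4 D)),  t_D = 10 h

is 1 for v = 0, 0 for D = 0 with v > 0, and undefined (flagged, excluded
from summaries with the exclusion counted) for a stationary fit D = v = 0.

The coefficient 4 D (the 2D convention) is applied verbatim to 3D
displacements, matching the assay's original analysis. Consequently a pure
random walk generated with per-axis diffusion coefficient d_axis (3D MSD
6 d_axis t) is recovered as D = 1.5 d_axis. All tests and documentation use
this mapping explicitly. The unweighted quadratic fit has a small downward
bias on D for purely diffusive tracks (the spurious positive v² term
absorbs variance); at 72 hourly frames the median recovered D sits ~15–20%
below 1.5 d_axis, within the 25% envelope asserted by the tests.

Population summaries report median and SD (SD = 0 by convention for a
single fit, flagged). Group comparison of f_D uses Kruskal–Wallis followed
by Dunn's pairwise z-tests on mean ranks with tie correction; the default
adjustment is Bonferroni for consistency with the killing statistics. A
fully degenerate input (all values identical) is defined as H = 0, p = 1.
Killing dose–responses are compared by two-way ANOVA
(condition × concentration, OLS type-II) with Bonferroni-adjusted Welch
t-tests of each condition against the reference within each concentration;
identical zero-variance groups are defined to give p = 1.

## Synthetic assay generator

The generator emulates the statistical structure of the assay, not its
optics or biochemistry:

* **Geometry.** Nuclei are dart-thrown uniformly into a sphere (default
  radius 75 µm, i.e. a ~150 µm tumoroid) with a minimum spacing
  (default 7 µm); packing failure raises an explicit density error.
  Desk-scale defaults — 300 nuclei standing in for a ~5000-cell tumoroid,
  100 T-cells for ~50,000 added on the gel, a 400×400×200 µm volume at
  2 µm/px and 10 µm z-step, 72 hourly frames — keep a full scenario within
  minutes on one CPU; the scaling is recorded in the written config.
* **Motion.** Cells advance in fixed 0.1 h sub-steps, sampled at the frame
  interval. Diffusion is per-axis Gaussian with variance 2 d_axis dt
  (default d_axis 2 µm²/h, i.e. fitted D ≈ 3 µm²/h, a realistic magnitude
  for T-cells in collagen at hour-scale sampling). Recruitment is a binary
  switch rather than a chemokine PDE: in `on_first_contact` mode, the
  first T-cell–tumoroid contact turns on a drift of magnitude `speed`
  (default 6 µm/h) for all cells within the sensing radius. Drifting cells
  head for the tumoroid surface; on reaching the boundary zone they head
  for the nearest live nucleus (infiltration); when no live nuclei remain
  the drift reverses outward. This egress rule emulates the experimentally
  observed loss of T-cell localization once killing is complete and is
  what produces the peak-then-decline recruitment curve. Modes `never`
  (pure diffusion) and `always` (drift from t = 0, useful for ballistic
  limits) complete the set. Boundaries reflect, preserving cell counts.
* **Killing.** A live nucleus simultaneously contacted by at least
  `contacts_required` T-cells (default 1, contact radius 10 µm) dies with
  hazard `kill_rate_per_contact` (default 1/h); PI renders
  `pi_onset_delay` (default 1 h) after death.
* **Initial layout.** Most T-cells start in a thin layer under the top gel
  face (`offset-top` confines the layer to one lateral half, the tilted-gel
  layout); a few seed-contact cells (default 5) start in the contact band
  at the tumoroid boundary, emulating the cells that have already reached
  the tumoroid when time-lapse acquisition starts. Effective and
  ineffective presets share identical geometry and baseline motility and
  differ only in the recruitment switch and kill rate.
* **Rendering.** One Gaussian blob per object per channel (defaults:
  σ_xy 3–4 µm, σ_z 5–6 µm, amplitude 1000 over background 20), sampled at
  voxel centers, plus optional Poisson shot noise. Blob widths below one
  pixel (laterally) or half a z-step (axially) are clamped with a warning.
  Noise levels are free parameters chosen so that default segmentation
  operates comfortably; no claim of optical realism (no PSF asymmetry,
  bleaching, drift or fiber background) is made.

What passing tests on this generator do **not** show: robustness to real
microscopy artifacts (uneven illumination, debris, optical sectioning
cross-talk), to densely clustered T-cells inside the tumoroid (detections
can merge), or to non-convex or fragmenting tumoroids (the convex-hull
boundary would overestimate such shapes).

## Numerical and degenerate-input conventions

* Deterministic everywhere: fixed seeds give bit-identical ground truth,
  stacks and CSV outputs (floats serialized at %.17g and parsed
  round-trip).
* Labels are renumbered in raster order of first occurrence so segmentation
  output is order-stable.
* The in-tumoroid count of a handful of boundary cells quantizes noisily
  (±2) because each cell spans 1–2 z-sections; tests of the quiescent
  scenario therefore use the seeded boundary population as the baseline for
  the no-surge check rather than a single-frame count.
* Validation errors are raised before any computation for inverted volume
  gates, non-positive calibrations, out-of-range parameters and unknown
  config keys. The CLI maps validation errors to exit code 2 and runtime
  failures to 3.

## Problem sizes

Tests and the acceptance script use: 200-cell populations at 72 frames for
parameter recovery; the full 300-nucleus/100-T-cell desk-scale scenario
pair (72 frames each) for the end-to-end contrast; 50 random trajectories
of ≤30 points for the MSD oracle; and ≤4 detections per frame for the
exhaustive linking optimum. These sizes were chosen so the whole suite
runs on a single CPU in minutes while keeping the stochastic assertions'
sampling error well below their tolerances.
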