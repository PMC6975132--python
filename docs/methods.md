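# Methods

This note documents the models, parameters, and numerical choices behind
`fmvm`, and what its synthetic-data tests do and do not demonstrate.

## Imaging model and the synthetic video generator

The simulator emulates violet-light (420 nm) skin capillaroscopy on a
monochrome sensor (default geometry 744×482 px at 60 fps; the test scenes use
256×256 crops to keep runtimes small).  A scene is a bright tissue background
of constant level *B* (default 200 intensity units on an 8-bit-like scale)
carrying one or more capillaries, each defined by:

| parameter | meaning | default |
|---|---|---|
| `centerline_control_points` | (row, col) points in μm; the tube centerline is a cubic parametric spline through them | — |
| `tube_width` | inner tube diameter, μm | 10 |
| `velocity` | signed flow speed, mm/s (positive = start → end) | 1.0 |
| `rbc_length` | along-flow FWHM of one cell's absorption profile, μm | 12 |
| `rbc_spacing` | mean center-to-center cell gap, μm | 80 |
| `rbc_contrast` | fractional intensity dip of a cell vs. background | 0.5 |
| `rbc_spacing_jitter` | fractional jitter of each gap | 0.2 |

Rendering uses intrinsic tube coordinates: for every pixel the nearest point
of the densely resampled centerline (0.25 px arc steps, KD-tree lookup)
gives a perpendicular distance and an arc position.  An RBC centered at arc
position *s₀* darkens the image by
`contrast · B · exp(−½(Δs/σ∥)² − ½(d⊥/σ⊥)⁴)` — Gaussian along the flow
(FWHM = `rbc_length`, so sub-pixel motion produces smooth streaks) and
flat-top quartic across it (half-maximum at the tube radius, because a cell
fills the vessel cross-section and the wall is sharp).  The vessel wall
itself is shaded by `0.25 · rbc_contrast · B` with a 1-px soft edge, giving
the polarity every stage relies on: RBC < tube band < background.  Additive
Gaussian sensor noise (sd `noise_sd`, default 2; the test suites use 5 ≈
2.5% of background as "moderate") is applied last.  All randomness comes
from one seeded generator: identical configurations render bit-identical
videos.

Cell trains are irregular on purpose: gaps are jittered around
`rbc_spacing`.  A perfectly periodic train observed at 60 fps is temporally
aliased whenever the per-frame displacement is commensurate with the
spacing — at 2.2 mm/s a cell advances ≈ 37 μm per frame, so an 80-μm
periodic train would be indistinguishable from a slower counter-propagating
one, an ambiguity no slope estimator can resolve.  Physiological trains are
irregular, which removes it.  The default spacing (80 μm) keeps consecutive
streaks separable across the whole 0.1–2.2 mm/s physiological range at
60 fps.

What the simulator does **not** model: optical point-spread blurring,
pulsatile (time-varying) flow, cell deformation, probe motion jitter, and
photon (signal-dependent) noise.  Passing tests therefore demonstrate
correctness of the measurement chain under constant flow and additive noise,
not robustness to motion artifacts or pulsatility in clinical recordings.

## Detection

`detect_threshold` flattens the background (large-kernel Gaussian, default
25 px, minus a lightly denoised copy, σ = 1.5 px), thresholds by Otsu
floor-guarded at 4 robust sigmas (1.4826·MAD), and grows the seeds by
hysteresis down to `max(0.5·threshold, 3σ)` so the faint vessel band joins
the dark cell cores into one component per capillary.  The noise-floor guard
is what reproduces the low-SNR failure mode: a capillary whose contrast sits
below the sensor noise yields no seeds and is missed, while a structure-free
frame yields no detections at all.  `detect_framediff` averages
|I_t − I_{t−gap}| (default gap 2 frames ≈ 33 ms at 60 fps) over all pairs and
thresholds at median + 4·MAD; a stalled capillary produces no response and
is missed — the second documented failure mode.  Externally produced boxes
(CSV/JSON, schema `row_min,col_min,row_max,col_max,score,label`, half-open
pixel coordinates) bypass both.

Matching predictions to ground truth is greedy in descending IoU with an
0.5 default threshold, one truth box per prediction.  Because real (and
simulated) capillary truth boxes are disjoint, a prediction cannot reach
IoU ≥ 0.5 with two truths at once, so greedy matching attains the
exhaustive-assignment optimum; the tests verify this on randomized small
instances.  Rates are reported to one decimal in percent; the
false-positive rate may exceed 100% when false detections outnumber truths,
since its denominator is the truth count.

## Skeletonization and path extraction

Segmentation operates on the temporal-minimum projection by default (moving
cells darken the whole tube over a 2-s clip), color-reversed so the vessel
is bright, with the same hysteresis scheme (weak = 0.5·Otsu, floored at
median + 3·MAD); an ROI whose Otsu threshold does not clear median + 4·MAD
is rejected as containing no vessel.  The weak fraction of 0.5 was chosen to
place the mask boundary at the rendered vessel wall (half-maximum of the
cell profile), which the segmentation oracle test (≥ 90% tube coverage,
≤ 10% spill) pins down.

Thinning is scikit-image's homotopic skeletonization (Lee variant), which
in practice is idempotent, one-pixel wide (no 2×2 foreground block) and
topology-preserving — properties the suite asserts on random blob masks.
Path extraction builds an 8-connected pixel graph with a corner-cut rule
(a diagonal edge is dropped when a shared 4-neighbor exists), prunes spurs
shorter than `min_spur_um` (default 10 μm; thinned real vessels always
carry short spurs) shortest-first until two endpoints remain, and orders
the walk from the lexicographically smaller endpoint so the traversal —
and hence every velocity sign — is deterministic.  A skeleton that reduces
to a cycle, or that keeps a branch longer than the spur threshold, raises a
typed error instead of guessing a traversal; the full-field driver records
such capillaries as failures rather than dropping them.

One numerical subtlety: the chain-code length of a digital curve
(1 / √2 steps) overestimates oblique segments by up to ≈ 8%, which would
stretch the kymograph's space axis and bias every velocity by the same
factor.  The ordered chain is therefore smoothed with a small Gaussian
(σ = 2 px) before arc length is accumulated; padding by point-reflection
about the endpoints keeps straight and diagonal lines — and the endpoint
positions — exact, and the velocity-recovery tests show the residual length
bias is below 2%.

## Kymograph and streak velocimetry

The path is resampled at uniform arc steps of one pixel-equivalent (the
step is total length/(n−1), within a fraction of a percent of `um_per_px`;
the grid includes both endpoints so reversing the path flips the diagram's
rows exactly, making slope antisymmetry under path reversal testable to
machine precision).  Frames are sampled by bilinear interpolation — nearest-
neighbor sampling would quantize sub-pixel motion and corrupt low-velocity
slopes.

Automatic streak fitting proceeds in four steps:

1. smooth (σ = 1 px) and contrast-normalize per column (subtract the column
   median);
2. label dark pixels below the per-column `dark_quantile` (default 0.2)
   that are also below a floor of `max(robust σ, 5% of the deepest dip)` —
   the floor keeps blank columns and faint Gaussian tails out of the point
   clouds, whose asymmetric clipping at the diagram edges would otherwise
   bias steep fits;
3. form connected components in a shear-compensated frame: at 2.2 mm/s a
   streak advances ≈ 37 px per column and is not 8-connected in raw pixels.
   The coarse shear slope is the peak of the averaged cross-correlation of
   adjacent darkness columns (parabolically refined to sub-pixel), then
   iteratively re-estimated from the fitted streaks.  A 1-px dilation in
   the sheared frame merges fragments adjacent within one pixel — unresolved
   cell pairs form one wide streak whose slope is still the velocity;
4. fit each component spanning ≥ `min_streak_len_frames` (default 5)
   columns by darkness-weighted total least squares in the (time, space)
   plane, and convert slope to μm/s via the metric steps.

The per-capillary estimate is the mean of streak slopes in mm/s with the
sample standard deviation across streaks as the dispersion (the ± convention
of this package; only means enter any comparison).  Direction is "forward"
/ "backward" by the sign convention above, "mixed" when streak signs
disagree.  A brute-force Radon-style orientation search (maximizing the
line-integrated darkness over a slope grid) exists in the test suite only,
as an independent oracle; the acceptance suite requires 2% agreement on
noise-free single-streak diagrams.

Manual fitting (`fit_streak_manual`) reproduces the classic two-point
procedure: slope = Δs·space_step / (Δt·time_step).

## Full-field driver, statistics, limits

`run_pipeline` detects (or accepts) boxes on the middle-index frame,
processes each box independently through the stages above, and reports
per-capillary velocities plus the field mean and (population) variance of
the per-capillary means; failures carry their stage and reason.  Reported
velocities are rounded to one decimal in mm/s in the CSV summary — the
conventional precision for these measurements — while the JSON report keeps
full precision so round-trips are exact.

The measurable range is [δ·f, L·f]: slower than one optical-resolution
element (δ, default 0.18 μm) per frame is sub-resolution motion; faster
than the observable vessel length (L) per frame means a cell crosses the
whole vessel between frames.  At δ = 0.18 μm, L = 400 μm, f = 60 fps this
is 0.01–24.0 mm/s.  The coincidence between two velocity lists is the mean
of per-pair min/max ratios in percent, rounded to the nearest integer — a
symmetric agreement measure that cannot exceed 100%.

## Problem sizes and defaults in the test suite

End-to-end tests use 256×256 px, 120-frame (2 s at 60 fps) videos with
noise sd 5 and one to four capillaries — small enough for the whole suite
to run in about two minutes on one core while exercising every stage at
realistic contrast.  Velocity recovery is asserted within 10% at
v ∈ {0.1, 0.3, 0.6, 1.0, 1.5, 2.2} mm/s (measured errors are ≤ 2%);
orientation invariance of the estimate is below 3% by construction of the
rotation-equivariant renderer.

## Known limitations

- Branching or crossing capillaries are rejected, not traversed; hairpin
  (non-crossing) loops are handled.
- Velocities are assumed constant per capillary over the clip; pulsatile
  flow would smear streak slopes and inflate the reported dispersion.
- The automatic fitter needs streaks spanning at least
  `min_streak_len_frames` columns; velocities far above L·f/‖path‖ per
  frame leave too few samples and raise a "no streaks" error rather than
  returning a confident wrong estimate.
- Calibration (μm/px) is an explicit required input; nothing in the video
  itself determines optical magnification.
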