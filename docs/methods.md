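# Methods

## The measurement problem

Movement sense (the kinaesthetic component of proprioception) of the wrist
can be assessed by asking a person to trace a printed target line with a
hand-held laser pointer while a fixed camera films the target board.  The
test scored here uses an A3 board (420 × 297 mm, landscape) carrying a 1 mm
thick black zig-zag center line with a total trace length of 1 m, filmed at
1280 × 720 px, 30 fps, 24-bit color.  Each trial yields two outcomes:

* **Acuity** — the percentage of the trial time during which the laser dot
  touches the black line;
* **Speed** — the average movement speed of the dot in mm/s.

A session comprises both hands × both drawing directions × three trials
(12 trials).  The drawing direction combines with the hand into an
anatomical movement label: a clockwise (left-to-right) trace is *palmar*
for the left hand and *dorsal* for the right, and vice versa for
anticlockwise.

## Scoring pipeline

**Pattern model.**  The apex coordinates of the printed zig-zag are not a
published quantity, so the pattern is a parameterized model constrained by
the printed facts: board size, 1 mm line width, 1 m trace, horizontal
orientation, center cross at the arc-length midpoint.  The default is a
5-segment zig-zag spanning 400 mm horizontally; the level separation
(amplitude) follows in closed form from the trace-length constraint,
`a = sqrt((L/n)² − (span/n)²)` ≈ 183.3 mm, which fits inside A3.  Geometry
that admits no such amplitude (or pushes apexes off the board) is rejected.

**Corner detection.**  Done once per session on a reference frame:
grayscale conversion (Rec. 601 luma), a dark threshold restricted to the
green board region (largest green-dominant connected component, holes
filled; threshold default Otsu over that region), then the four most
distant on-pixels along the diagonals — up-left = argmin(x+y), up-right =
argmax(x−y), down-left = argmax(y−x), down-right = argmax(x+y).
Red-dominant pixels are excluded first so the dot cannot perturb the
corners.  The default reference frame is the *middle* of the stream: at
trial start the dot sits on a terminal corner of the line, and even with
red exclusion the hole it bites would shift that diagonal extreme by about
a dot diameter.

**Calibration.**  The four detected pixel extremes are matched to the mm
positions of the polyline vertices that are extreme under the same four
diagonal functionals, and an exact-fit 4-point plane homography (pixel →
mm) is estimated.  A projective map, not a similarity, because the camera
sits behind and lateral to the shoulder and sees the board under
perspective.  The RMS reprojection of the four corners is reported as a
sanity value.  Lens distortion is not modeled.

**Dot detection.**  Per frame: red-dominance binarization
(`R ≥ t_abs` and `R − max(G,B) ≥ t_margin`, defaults 150/60), with
near-saturated pixels (`R ≥ 245`) accepted regardless of margin because
real laser dots bleach to a white-pink core; then artifact clearing and
component selection.  Clearing is *opening by reconstruction*: a 3 × 3
binary opening decides which components survive, but a surviving component
keeps its exact pre-opening pixel set.  A plain opening would erode the
dot's boundary pixels — precisely the pixels that decide a marginal
line-touch — and measurably biases Acuity low.  Components outside the
[10, 5000] px area band are discarded and the largest survivor is kept.
An undetected dot (occlusion by hair or shoulder, dot off the board) is a
valid observation with all measurement fields absent, never zero-filled
and never silently interpolated; an optional config-gated gap fill
(≤ k frames, logged) interpolates only the mm centroid.

**On-line classification.**  A dot touches the line when its pixel set
shares at least one pixel (configurable) with the line mask — the set of
pixels whose center, mapped to board mm, lies within half the line width
of the center polyline, plus a tolerance.  The default tolerance is a
quarter of a pixel side (in mm at the board scale).  Rationale: both the
dot raster and the mask are sampled at pixel centers, so the discrete
overlap test is systematically *stricter* than the continuous
"dot-disk-intersects-line-band" criterion; the mean one-sided quantization
margin of a uniformly placed region boundary is a quarter of the pixel
pitch.  Measured on synthetic scenes at 1280 × 720 (≈ 2.3 px/mm), zero
tolerance biases Acuity by −0.3 to −4 percentage points depending on the
lateral-error level, while a quarter-pixel tolerance leaves |bias| ≲ 1
point.  Setting the tolerance to 0 restores the raw overlap rule.

**Trial segmentation.**  The dot's distance to the terminal corners of the
polyline defines the trial window: the start frame is the last frame of
the first run of ≥ `dwell_frames` (default 5) consecutive frames within
`radius_mm` (default 10 mm) of the start corner — i.e. the moment of
sustained departure — and the end frame is the first frame of the first
subsequent such run at the end corner.  The dwell requirement suppresses
single-frame grazes and detection flicker at the termini.  Which physical
corner is "start" follows from the drawing direction (clockwise ⇒ leftmost
terminus).  A trial whose dot never dwells at a terminus raises a
segmentation error naming the failing terminus.

**Acuity.**  100 × (frames on-line) / (frames in window).  Undetected
frames count in the denominator (scored off-line) because the outcome is
defined over trial *time*; a config switch restricts the denominator to
detected frames, and the per-trial report always carries
`n_frames_detected` so either convention can be recomputed.

**Speed.**  Default: arc length of the detected centroid trajectory
(consecutive mm displacements; undetected gaps bridged by straight
segments) divided by the window duration.  No trajectory smoothing is
applied by default (`smooth_window = 1`): the reference quantity is the
raw path length of the dot, and even a 3-frame moving average measurably
shortens a temporally correlated lateral error path (by ~8–19% under the
generator's AR(1) error model), which would put the estimate outside the
5% band around the true arc length.  A window is still configurable for
noisy detectors.  A "nominal" mode (trace length / duration) is provided
because a fixed-path definition is also defensible; both speeds are
emitted in the trial table.

## Synthetic scenes and what they do (not) show

The generator renders the physical setup: gray background, green board
quadrilateral under a mm→px camera homography (default: mild keystone +
1.5° rotation), rasterized black center line, and a red dot with a
saturated core advancing along the path.  Motion model per frame at
30 fps: tangential speed ~ N(mean, jitter) truncated at 0 (defaults
55 ± 5 mm/s, a self-paced trace of ≈ 18 s); lateral error an AR(1) process
(stationary SD default 2 mm, correlation 0.9) applied along the local
normal — correlated, as tremor and corrective movements are, which
stresses the run-length behavior of the on/off-line classifier.  The dot
dwells 1 s at each terminus.  Additive Gaussian pixel noise (SD 3).
Everything derives from one seed; frame `i`'s noise generator is seeded by
`(seed, i)`, so streaming and random access are bit-identical.

Ground truth is analytic: per-frame true center (mm and px), lateral
distance to the polyline, on-line flag (distance ≤ dot radius + half line
width), trial window (same dwell rule as the segmenter applied to the true
path), and true arc length (sum of raw consecutive displacements).

The cohort generator is parametric (no rendering): subject-level acuity
and speed are a correlated bivariate normal (ρ = −0.65, the
speed-accuracy trade-off), with a dominant-hand gain (+5 points), an
optional pain deficit on the affected hand (−6), a per-trial learning
shift (+1), and i.i.d. trial noise (SD 5.5); between-subject SD 10 around
a mean of 70.  With those defaults the implied within-condition ICC is
σ_b²/(σ_b² + σ_e²) ≈ 0.77 and the implied SEM ≈ 5.5 — the plausible range
for this kind of test.

What passing synthetic tests does **not** show: robustness to real-world
lighting gradients, lossy video compression, motion blur, camera shake,
non-red lasers, or occlusions with structured timing.  The detector
thresholds are declared defaults validated on these scenes, not values
recovered from any particular recording setup.

## Reliability statistics

All repeatability quantities come from one two-way decomposition of the
complete subjects × trials matrix (rows = subjects, columns = trials):
MS_rows, MS_cols, MS_error with (n−1), (k−1), (n−1)(k−1) df.  Using a
single decomposition guarantees the ICC and the RM-ANOVA can never
disagree about the variance components.

* **ICC, single measures, two-way random effects.**  Consistency form
  `(MS_R − MS_E) / (MS_R + (k−1) MS_E)` and absolute-agreement form
  `(MS_R − MS_E) / (MS_R + (k−1) MS_E + k (MS_C − MS_E)/n)`.  Both are
  always reported side by side because the conventional labels are easily
  mixed ("ICC(2,1)" usually denotes absolute agreement, while "two-way
  random consistency" names the consistency form).  95% CIs use the
  F-distribution method: exact for consistency, Satterthwaite-df
  approximation for agreement.  Values and CIs match `pingouin`'s
  ICC(C,1)/ICC(A,1) to machine precision on test fixtures.
* **SEM** = SD(consecutive-trial differences)/√2, with the per-subject
  difference sets (t2−t1, t3−t2) pooled into one vector by default; a
  "mean of per-pair SEMs" variant is available.  The CI is a χ² interval
  on the SD of the pooled vector (the pooled differences are not fully
  independent, so this interval is mildly approximate).
* **RM-ANOVA** on the trial factor: F = MS_C/MS_E with (k−1, (n−1)(k−1))
  df, sphericity assumed; an optional Greenhouse–Geisser correction is
  off by default.  MS_E = 0 with a nonzero trial effect reports F = ∞,
  p = 0 (a perfect systematic effect).
* **Spearman** rank correlation (speed–accuracy trade-off), **paired /
  Welch t-tests** with CIs, and the **Shapiro–Wilk** normality screen are
  delegated to `scipy.stats`; degenerate inputs (constant vectors,
  zero-variance differences) are rejected or flagged rather than reported
  with spurious statistics.  No multiplicity correction is applied by
  default; a Holm adjustment is available by flag.

Missing trials: listwise deletion (with a reported count) for ICC, SEM and
RM-ANOVA; available-case means for condition aggregation.

## Numerical choices and degenerate inputs

* Coordinate convention, used everywhere: origin top-left, x rightward,
  y downward, pixel centers at integer coordinates; points are (x, y).
* Homography estimation is an exact fit on 4 correspondences
  (`skimage.transform.ProjectiveTransform`); collinear or coincident
  corners raise a calibration error, as does a singular matrix.
* The zig-zag length constraint is enforced at 1e-6 relative tolerance;
  pixel→mm→pixel round-trips hold to < 1e-6 px for non-degenerate maps.
* Trial scoring is fully deterministic: identical frames + config give
  bit-identical results (no RNG anywhere in the scoring path).
* Undefined statistics raise typed errors: ICC on zero total variance,
  Spearman on constant vectors, Shapiro–Wilk outside 3 ≤ n ≤ 5000.

## Problem sizes used in the shipped checks

The test-suite and the acceptance script validate end-to-end recovery at
the full recording resolution (1280 × 720, 30 fps) with a 80–100 mm/s
trace (≈ 10–12 s per trial, ~350–500 frames) across lateral-error SDs
0–4 mm; unit-level end-to-end tests use a 640 × 360 reduced scene
(≈ 1.1 px/mm), where the coarser raster widens the achievable Acuity
agreement to about the half-pixel band (~5 points).  Statistical
parameter-recovery and power checks use the study-sized design (n = 50
subjects, k = 3 trials) with 100–400 replicates.

## Known limitations

* Single red dot only; no multi-dot tracking, no other laser colors.
* No lens-distortion correction; a plane homography assumes a flat board.
* The printed zig-zag's true apex layout is unknown; all geometry-
  dependent defaults are explicit parameters, not claims about the
  original physical board.
* Real-recording robustness (compression, lighting, blur) is untested by
  construction; the synthetic scenes are clean by design.
* The SEM confidence interval treats pooled consecutive differences as
  independent draws, which overstates the effective df slightly for k = 3.
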