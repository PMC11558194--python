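# Methods

`casatrack` implements a computer-assisted sperm analysis (CASA) pipeline
for dark-field microscopy video — segmentation, particle filtering,
multi-object tracking and WHO-style kinematic parameters — together with a
synthetic data generator that makes every stage verifiable without clinical
semen recordings. This note documents the models, the defaults and the
choices made where the design was genuinely open.

## Motility parameters

For a head trajectory (x_j, y_j), j = 1..M, sampled at uniform inter-frame
time Δt, the per-track parameters are

- **VCL** (curvilinear velocity) = Σ_{j=1}^{M−1} ‖p_{j+1} − p_j‖ / ((M−1)Δt),
- **VSL** (straight-line velocity) = ‖p_M − p_1‖ / ((M−1)Δt),
- **VAP** (average path velocity) = the VCL formula applied to the 5-point
  moving-average path x̄_k = mean(x_{k−2}..x_{k+2}),
- **LIN** = VSL/VCL, **STR** = VSL/VAP, **WOB** = VAP/VCL.

All ratios are stored as fractions and scaled to percent only for
reporting. LIN = STR × WOB holds identically; ratios are undefined (and
reported as missing) for tracks with zero VCL or VAP.

Two conventions deserve note:

- **Clip duration.** A "1 s at 30 fps" clip is represented as 31 samples
  spanning 30 intervals, so (M−1)Δt = 1.0 s exactly. Every velocity
  denominator relies on this.
- **Smoother boundaries.** The 5-point window is undefined at the first and
  last two samples. We shrink the window *symmetrically* (sizes
  1, 3, 5, …, 5, 3, 1), which keeps the output length M, leaves the raw
  endpoints untouched, and therefore guarantees VSL ≤ VAP on every track
  (the smoothed path still connects the raw endpoints) and makes a straight
  constant-speed path exactly invariant (VAP = VCL = VSL). Asymmetric
  clamping of the window, the other natural reading, pulls the smoothed
  endpoints inward and biases VAP low on short tracks; it was rejected for
  that reason. VAP (and STR/WOB) require M ≥ 7 by default so the window has
  at least two fully interior points; VCL/VSL require only M ≥ 2.

The same formulas exist twice in the package: vectorised in
`casatrack.motility` (the production path) and as plain-loop summation in
`casatrack.kinematics.ground_truth_motility` (the oracle). The test suite
holds them to relative agreement < 1e−9 on 1,000 random tracks.

## Synthetic kinematics

No public dataset accompanies this kind of dark-field CASA instrument, so
the simulator is the reference against which recovery is measured. The
motion model is minimal but reproduces the qualitative structure of real
CASA populations (VCL > VAP > VSL, WOB < 1):

- centre path: constant-speed 2-D propagation with Brownian heading
  (variance `heading_diffusion`, rad²/s);
- head wobble: sinusoidal lateral displacement of amplitude
  `wobble_amplitude` (μm) at `wobble_frequency` (Hz) along the path normal,
  with a uniform random phase per sperm;
- an immotile fraction with zero progressive speed and no wobble;
- optional isotropic Gaussian positional noise per sample.

Speeds are drawn from a normal truncated at zero. Motion is strictly 2-D:
the 10 μm-deep counting chamber confines swimming essentially to the focal
plane. Tracks leaving the field of view are truncated at first exit rather
than reflected, which both mirrors reality and exercises variable-length
track handling downstream.

Defaults (`KinematicsParams`): progressive speed 25 ± 8 μm/s, wobble
2.5 μm at 10 Hz, heading diffusion 0.5 rad²/s, immotile fraction 0.2,
positional noise 0.1 μm. These are chosen once as plausible values for
moderately motile human sperm in a counting chamber (lateral head
displacement of a few μm, beat-coupled wobble near 10 Hz, curvilinear
speeds of a few tens of μm/s); they are population parameters, not fitted
quantities. The end-to-end validation scene instead uses 30 ± 5 μm/s with
2 μm wobble at 5 Hz and no immotile fraction, so that every simulated cell
should be recovered and the wobble is well resolved at 100 fps.

**Temperature model.** Mean progressive speed responds linearly,
`mean += slope × (T − T_ref)` with defaults T_ref = 26 °C and slope
1 (μm/s)/°C; wobble parameters are unaffected (observed head-wobble
amplitude does not change appreciably with chamber temperature). The
temperature-sweep recipe evaluates the grid {26, 28, 30, 32, 34, 37} °C
with common random numbers — the same seed at every temperature — so the
trend estimate is not masked by sampling noise, and a zero-slope model
yields an exactly flat profile. Note that the recovered VCL-vs-temperature
slope is smaller than the input speed slope because VCL also contains the
(temperature-independent) wobble contribution.

## Dark-field rendering

Heads are rendered as anisotropic 2-D Gaussians oriented along the
instantaneous heading. The half-maximum contour is an ellipse with the
configured semi-axes (default 2.0 × 1.25 μm, nominal apparent area
π·a·b ≈ 7.9 μm², inside the 3–30 μm² particle band). Only blob shape and
SNR matter downstream, so no textured sperm image or tail is rendered;
photometric defaults are background 20, head peak 200, additive Gaussian
read noise σ = 5 on an 8-bit scale at 0.5 μm/px. Shot noise is omitted;
SNR is controlled through the peak intensity instead.

Distractors emulate debris and out-of-focus particles in two classes: dim
small specks (areas 0.5–2 μm², peak 15 over background — below any
sensible threshold) and bright large debris (40–80 μm²), both outside the
particle-filter band, static up to a per-frame jitter. Distractor
placement keeps a configurable clearance (default 12 μm) from all sperm
positions so that specificity tests measure the area filter, not blob
merging — merge/split handling is explicitly out of scope for the tracker.
The read-noise and distractor random streams are split independently from
the seed, so enabling distractors does not perturb the noise field.

What the fixtures do *not* emulate: focus drift, tails, halo artefacts,
intensity variation between cells, shot noise, and collisions. Passing
recovery tests therefore demonstrates correctness of the algorithms under
the stated imaging model, not clinical performance on real semen video.

## Detection

Dark-field frames are thresholded per frame and 8-connected components
extracted with intensity-weighted (sub-pixel) centroids; apparent area is
pixel count × (μm/px)². The particle filter keeps components with area in
the closed interval [3, 30] μm².

The default threshold is **three-class multi-Otsu**, taking the upper class
boundary. Sperm heads occupy well under 1% of the pixels of a dark-field
frame; classic two-class Otsu then tends to split the background noise
distribution instead of separating the heads (measured on the default
fixture: threshold ≈ 20 on a background-20/peak-200 frame, flooding the
mask). Reserving one class for the bright heads fixes this while remaining
deterministic and parameter-free. Two-class Otsu and a fixed threshold
remain available in `SegmentationConfig`, along with an optional
pre-threshold Gaussian blur (off by default). A constant frame has no Otsu
threshold and yields an empty mask with a warning.

Coordinate convention, used everywhere: 0-based pixel indices, x = column ×
pixel size, y = row × pixel size, origin at the centre of pixel (0, 0).

## Tracking

Consecutive frames are linked by gated globally-optimal one-to-one
assignment (`scipy.optimize.linear_sum_assignment`) under Euclidean
centroid distance: out-of-gate pairs get a prohibitive cost, so the
optimiser maximises the number of within-gate matches and, among those,
minimises total distance. This is deterministic and resolves crossings
that greedy nearest-neighbour linking mis-assigns; the test suite checks
it against exhaustive enumeration on scenes of up to 4 objects.

Defaults: gate = 100 μm/s × Δt × 2 (twice the per-frame displacement of
the fastest plausible sperm; ~2 μm at 100 fps), no gap closing
(`max_frame_gap = 0` — interpolating across gaps would feed invented
positions into the velocity formulas), minimum track length 2. Tracks are
renumbered densely in creation order after discarding short ones.
Detections are canonically sorted by centroid within each frame before
assignment, so the output does not depend on input ordering; exact cost
ties between distinct optimal assignments (a measure-zero event for
floating-point centroids) are resolved by the assignment solver's
deterministic choice.

## Method-comparison statistics

Agreement between two trackers on paired per-track (or per-field) values is
summarised by CV% = 100 × SD(a − b) / mean(a ∪ b), with the sample SD
(n−1). "Overall mean" is read as the pooled mean of both methods, which
makes the statistic symmetric; when the methods agree to within a few
percent the alternative reading (one method's mean) changes the CV by less
than 2%. Group comparisons use the pooled-variance two-sample t-test
(Welch available via a flag) and one-way ANOVA, via `scipy.stats`.
Shapiro–Wilk and Levene pre-checks are logged as advisory diagnostics, not
used to branch.

## Illumination geometry

An LED on a ring of radius r at board distance d illuminates the sample at
α = arctan(r/d) (point-source geometry; no refraction through the chamber
is modelled). With objective acceptance half-angle θ = arcsin(NA), a
pattern is bright-field if every active LED has α < θ, dark-field if every
LED has α > θ, and mixed otherwise; α = θ is treated as mixed-contributing
because marginal rays are not collected reliably.

The physical ring pitch and board distance of such instruments are rarely
published; the defaults here are pitch 8 mm and distance 40 mm, chosen so
that at NA = 0.3 the centre LED and first annulus are inside the
acceptance cone (bright field) while rings 3–5 — including the third ring
conventionally used for dark-field sperm imaging — are outside. (A 4 mm
pitch at the same distance would put the third ring at 11.3° < θ = 17.5°,
i.e. bright field, contradicting that behaviour.)

## Problem sizes in the validation suite

The end-to-end scene uses 50 sperm in a 768 × 768 μm field (1536 × 1536 px
at 0.5 μm/px), 1 s at 100 fps, spawned with ≥ 60 μm initial separation; the
frame-rate study subsamples that clip to 50/20/10 fps; reproducibility
renders it twice with different noise seeds; the area-filter study uses 20
sperm plus 100 distractors over 0.3 s; the temperature sweep uses 40 sperm
per chamber at 30 fps. These sizes keep the whole suite to a couple of
minutes on one CPU while leaving every population statistic well
determined.

## Known limitations

- The tracker has no motion model, no gap closing by default, and no
  merge/split handling; dense scenes with frequent collisions will
  fragment tracks.
- VAP's smoothing window is fixed at 5 points regardless of frame rate, so
  VAP at 10 fps smooths over 0.5 s while VAP at 100 fps smooths over
  0.05 s — the same convention as standard CASA practice, but worth
  remembering when comparing across rates.
- ALH, BCF, MAD and WHO progressive/non-progressive grading are not
  implemented.
- The renderer's photometric model is deliberately simple; it validates
  geometry and tracking, not detector physics.
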