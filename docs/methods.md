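# Methods

This note records the models, conventions and design choices behind
`romagree`, in the order data flows through the package.

## Body frame and angle definition

Skeleton positions live in a body-centred frame: **x** points to the
subject's left, **y** up, **z** from the subject toward the sensor (the
protocol has the subject standing facing the camera, so +z is the
subject's forward). The anatomical planes are coordinate planes of this
frame — sagittal keeps (y, z), frontal keeps (x, y), transverse keeps
(x, z) — and projection is a coordinate drop.

For a movement, the *measurement vector* connects the proximal to the
distal catalog joint: shoulder → elbow for shoulder elevation
movements, elbow → wrist (the forearm) for the four rotation
movements, hip → knee for the hip, spine-base → spine-mid for the
lumbar spine. The angle is the signed in-plane angle from the
movement's *zero reference* (straight down (0,−1,0) for shoulder/hip
elevation, trunk-up (0,1,0) for lumbar movements, forearm-forward
(0,0,1) for rotations) to the projected vector, computed with the
two-argument arctangent and multiplied by a per-movement sign so the
movement's own direction reads positive. The angle is invariant under
positive scaling of the vector, so limb length never matters.

The catalog (`movements.yaml`) stores sided movements for the right
side; the left side is obtained by substituting joint names, negating
the zero reference's x component, and flipping the sign when the plane
contains the x axis (mirroring reverses in-plane orientation in the
frontal and transverse planes but not in the sagittal plane). Axial
frontal-plane movements mirror onto their lateral counterpart
(left ↔ right lateral flexion).

The source the catalog derives from names measurement vectors only for
the elevation movements and never states projection planes per
movement; the rotation-movement vectors (forearm), their planes
(sagittal for rotations at 90° of abduction, transverse at 90° of
flexion) and all zero references are this package's own catalog
defaults, stored as data precisely so a user with different conventions
can override them per movement.

## Angle series processing

* **Missing joints.** A frame missing either required joint yields NaN;
  NaN runs of at most 5 frames (configurable) are bridged by linear
  interpolation, edge runs are held from the nearest computed angle,
  longer runs raise an error naming the joint. Missingness is always an
  explicit flag — never a silent zero position.
* **Unwrapping.** The instantaneous signed angle lives on (−180°, 180°];
  the per-frame series is unwrapped over time so a continuous sweep past
  180° keeps increasing. This is what makes the normal-range cap
  meaningful for hyperflexible subjects (a 186° abduction reads 186
  before capping, not 174).
* **Smoothing.** Exponential moving average with s₀ = x₀ and
  s_t = α·x_t + (1−α)·s_{t−1}. The smoothing constant is not documented
  for the emulated device; the default is α = 0.3, exposed everywhere,
  and exactness tests use α = 1 (the identity). Output is a convex
  combination of inputs, so smoothing can never overshoot the observed
  range.
* **ROM.** The maximum of the smoothed series. The cap (180° shoulder
  flexion/abduction, 90° for the two external rotations) is applied to
  the final maximum, not per frame — capping per frame would distort
  the velocity profile, and only the endpoint is reported clinically.
  Results are rounded to 0.1°, the device's display resolution.
* **Angular velocity.** Backward finite differences; the first sample
  has no predecessor and is defined as 0 (configurable to repeat the
  second sample). Duplicate timestamps are an error, not a warning.

## Reliability statistics

All statistics operate on an n × k table (cases × measurements; k = 2
throughout the shipped pipeline).

**ANOVA.** The two-way crossed decomposition without replication:
SSR (rows/cases), SSC (columns/measurements), SSE = SST − SSR − SSC,
with df n−1, k−1, (n−1)(k−1). SSE is clamped at 0 against negative
floating-point residue.

**ICC.** Two-way *random*-effects, absolute-agreement forms. The
single-measure form ICC(2,1) rates one measurement; the average-measure
form ICC(2,2) rates the mean of the k measurements. The prose the
package emulates says "two-way mixed … for absolute agreement" while
writing ICC(2,·), the random-effects notation; the estimates coincide
for these forms, and the random-effects absolute-agreement formulas are
what is implemented. The 95% CI for the single form is the F-based
construction with a Satterthwaite df for the column/error mixture; the
average-form CI applies the Spearman–Brown step-up to the single-form
bounds. Simulation at n = 70, k = 2 puts empirical coverage at
0.946–0.959 across true ICC 0.5–0.95 (the acceptance suite re-checks
bias ≤ 0.02 and coverage ∈ [0.93, 0.97] at 1000 replicates per value).
Degenerate inputs (constant matrix, zero denominator) raise an explicit
error rather than propagating 0/0.

**Grading.** poor < 0.50 ≤ fair < 0.75 ≤ good < 0.90 ≤ excellent. The
boundary values 0.75 and 0.90 are assigned to the higher class; the
emulated prose is ambiguous at the boundaries and a fixed convention
matters more than which one.

**Bland–Altman.** Differences d = x − y; bias d̄; s_d with the n−1
divisor; LOA = d̄ ± 1.96·s_d. The multiplier is fixed at 1.96 (not a t
quantile) — the printed LOA/SEM arithmetic this package reproduces is
only consistent with 1.96. The *agreement percentage* is the share of
differences falling **inside** the LOA, boundary inclusive; it is by
construction a multiple of 100/n, which doubles as an integrity check
on reported case counts.

**SEM and MDC95 — a deliberate naming trap.** Here SEM is the standard
error of the mean difference, s_d/√n, because that is the quantity the
emulated report tables tabulate (their MDC95 column equals
1.96·√2·(s_d/√n) cell for cell). This is *not* the classical
reliability SEM = SD·√(1−ICC), which is roughly √n/√2 times larger for
these designs. Users comparing MDC values across the reliability
literature must account for this; the ratio MDC95/SEM = 2.771859… is
exact by construction and audited on every emitted row.

**t-tests.** Both forms are provided. `paired_t_test` is the textbook
one-sample test on differences. `t_test_from_summary` is the pooled
two-sample statistic t = (m₁−m₂)/√((s₁²+s₂²)/n), df = 2n−2, computable
from printed summary rows; the emulated tables describe their test as
paired, yet every printed p-value reproduces under the pooled
summary-statistic form (47 of 48 rows to ±0.002; the remaining row
matches neither case count and is presumed a misprint). The package
surfaces both rather than silently resolving the discrepancy; table
verification uses the summary form.

**Lin's CCC.** 2·cov(x,y)/(var(x)+var(y)+(x̄−ȳ)²) with the n−1 divisor
used consistently; the divisor choice only matters against the squared
mean shift, and n−1 keeps it consistent with every other sample
statistic in the module.

## Pipeline conventions

* **Intra-device** analysis compares repetition 1 vs repetition 2 per
  device with the single-measure ICC; **inter-device** analysis
  compares the per-case means of the two repetitions per device with
  the average-measure ICC.
* Left and right sides are treated as independent cases (35 participants
  → 70 shoulder/hip cases). This mirrors the emulated design faithfully
  but violates independence — paired limbs share a subject — so ICC
  confidence intervals for bilateral joints are somewhat optimistic.
* Complete-case (listwise) deletion per movement: a case missing any
  required cell is dropped from that movement's analysis and the
  reported n is always the surviving count.
* Report columns are emitted in a fixed order; every row must pass the
  column-relation audit (LOA midpoint = bias; MDC95/SEM = 2.7719;
  agreement a multiple of 100/n).
* Normal-range caps can optionally be applied at ingestion
  (`cap_at_ingest`), since whether a recorded value was capped before or
  after transcription is an acquisition detail the table cannot reveal.

## Synthetic data

The measurement-table generator draws case truths θ_i ~ N(μ, σ_b²) and
observations y_ijd = θ_i + δ_d + γ_id + ε_ijd with ε ~ N(0, σ_e²),
device offset δ_d, and an optional case-by-device interaction
γ ~ N(0, σ_int²), then rounds to the device's granularity (0.1° for the
optical device, 1° for the goniometer; a 5° mode is available to mimic
goniometer readers' tendency to favour the marked 5° ticks). With
σ_int = 0 and rounding off the single-measure ICC is exactly
σ_b²/(σ_b²+σ_e²), giving a closed-form truth for recovery tests. Errors
are Gaussian — no distributional statement exists to emulate, and
normality is the canonical choice for angle-reading noise.

The per-movement study defaults (`STUDY_MOVEMENT_PARAMS`) are fixed
once: means and between-case SDs at normative standing-position
magnitudes for healthy adults (elevation arcs near 160–165°, mid-range
rotations, modest hip and lumbar arcs), within-case error SDs of
1.5–3.2°, and a hip-specific large device disagreement (offsets up to
9.4° and interactions of 7–9.5°) reflecting how unstable single-leg
standing movements are to measure. They reproduce the *orders of
magnitude* of the emulated study's dispersion and its qualitative
pattern (excellent intra-device, poor hip inter-device reliability) —
they are not a cell-by-cell calibration, which the unavailable raw data
cannot support.

The trajectory generator drives the movement's distal joint around its
fixed proximal joint with φ(t) = (peak/2)·(1 − cos 2πt/T) — zero to
peak and back, as the protocol prescribes — on top of a canonical
standing pose (fixed, anatomically proportioned, otherwise arbitrary
constants), carrying downstream joints rigidly, then adds i.i.d.
Gaussian position noise and per-joint dropout. The ground truth records
the noiseless sampled profile's maximum before the kinematics stage
ever runs, so round-trip tests genuinely exercise the vector/projection
path. With the default 4 s duration at 30 Hz a frame lands exactly on
the peak.

What the generator does **not** emulate: body sway and balance loss,
correlated (non-white) tracking noise, occlusion bursts tied to pose
rather than chance, soft-tissue artefact, or joint-limit coupling
between segments. Passing tests therefore demonstrate the correctness
of the computation chain under the stated error model, not the field
accuracy of any physical device.

## Problem sizes

The shipped analyses use the study's own dimensions (35 participants,
70/35 cases, k = 2). Parameter-recovery checks run 1000 replicates per
true-ICC value in the test suite and 500 in the acceptance script;
variance-structure checks use n = 5000 cases; Monte-Carlo noise bounds
use 25 seeded trace replicates. All random draws flow from explicit
seeds and the suite is deterministic.

## Known limitations

* Only complete two-device, two-repetition designs are orchestrated;
  the statistics layer accepts any k ≥ 2 but the pipeline does not.
* No clustering correction for bilateral measurements (see above).
* The F-based ICC interval assumes the two-way normal model; coverage
  under heavy rounding (1° goniometer granularity) is validated only
  empirically.
* The kinematics stage trusts its input skeletons; it does not attempt
  pose estimation, sensor calibration or coordinate-frame discovery.
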