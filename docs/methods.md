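# Methods

`gazebias` simulates and analyzes a closed-loop audio-visual search (AVS)
paradigm: an observer moves their gaze over a blank screen to find an
invisible circular target, guided only by a tone whose loudness encodes the
gaze-target distance. Targets occur twice as often in one hemifield, and the
learned spatial prior is measured as a shift of free-viewing behavior toward
the target-rich side. This note describes the models, the synthetic
observers, the numerical choices, and what the desk-scale results do and do
not show.

## Task model

**Geometry.** Coordinates are screen-centered degrees of visual angle
(+x right, +y up), computed from a 23.8-inch 1920x1080 monitor viewed at
57 cm via the exact relation `2*atan(size/2 / view_dist)`. At 57 cm, 1 cm on
screen subtends almost exactly 1 degree.

**Targets.** The grid crosses horizontal eccentricities ±{3.8, 11.4, 19.9}°
with vertical eccentricities {−7.5, 0, +7.5}°: 18 unique positions, target
radius 4.1°. The 180 training trials are allocated 90-60-30 over the three
left-to-right column-pair zones for a left-bias participant (mirrored for
right bias), giving a 2:1 hemifield ratio (120 of 180 targets on the biased
side). Within a zone, trials are spread as evenly as possible over its six
positions; the order is a seeded uniform permutation.

**Feedback.** Loudness is silent for distances at or below the target
radius, reaches full volume at 17.8°, and in between follows the normalized
exponential `v = (B^u − 1)/(B − 1)` with `u` the normalized distance and
base `B = e` by default. The base is configurable: the published description
fixes only "exponential" and the two endpoints, so the constant is a design
choice. Loudness at and beyond 17.8° is clamped to 1, which means feedback
carries no gradient out there — a property the search agent must cope with.

**Trial state machine.** A trial succeeds when gaze stays inside the target
disk for 500 ms of *continuous* dwell (the accumulator resets on exit;
tolerant variants are configurable) and times out at 10 s. `step_trial` is
the per-sample reference implementation; `run_trial` uses an equivalent
vectorized evaluator for cohort-scale work (their agreement is pinned by a
test).

## Synthetic observers

The original study records humans; here every participant is synthetic, so
each analysis can be exercised as a parameter-recovery problem.

**Search agent (run-and-tumble).** The agent alternates fixations and
saccades and reads the loudness only at fixation. If loudness fell since the
last fixation it keeps its heading (small angular jitter); if it rose, it
reverses course with larger angular scatter; if loudness is saturated (no
gradient), it falls back toward the screen center. Step size shrinks with
falling loudness (coarse-to-fine search), and silence makes it hold
position. The policy never sees target coordinates. Two learning mechanisms
operate across trials:

* a *hemifield prior* — an exponential moving average (rate 0.05) of the
  side on which targets appeared, which biases the direction of the first
  saccade of each trial (with the 2:1 distribution it converges to 2/3);
* *task skill* — a saturating proficiency term that shortens the initial
  central fixation (search-initiation latency), shortens fixations
  generally, and tightens re-orientation scatter.

These mechanisms are artifact choices (the source study does not model
human policy); they are the simplest pair we found that jointly reproduce
the qualitative signatures of the human data: within-trial distance descent,
across-trial descent, a bias-dependent learning curve, roughly 85–90% of
targets found, and mean search times of about 4 s.

**Free viewing.** Fixation durations are lognormal and saccade amplitudes
gamma, with "static" (long fixations, large steps) and "dynamic" (short
fixations, small steps) preset styles. Fixation centroids follow a
mean-reverting random walk whose stationary mean horizontal position equals
the style's `horiz_bias`; an `early_bias` term adds a natural early-viewing
offset to fixations starting within the first second. Saccades are 3-sample
position ramps — there is deliberately no main-sequence velocity model,
only enough kinematics for the velocity-threshold detector downstream.
Blinks are Poisson-inserted invalid runs.

**Transfer.** After training, a participant's free-viewing `horiz_bias` is
shifted by `transfer_gain * (2*prior − 1)` toward the trained side. The
population transfer gain of 1.5° (SD 0.9°, truncated at 0) yields a mean
induced shift of 0.5° at the converged prior of 2/3, matching the scale of
the published group effect (0.49°); the landmark-task transfer gain
defaults to 0, reflecting the null result on that task. Natural horizontal
biases are normal with mean −0.3° (mild pseudoneglect) and SD 1°.

**Landmark responder.** P(respond "right longer") is a two-parameter
logistic in the bisection offset; the generator is the exact inverse of the
fitted psychometric model (11 offsets spanning ±0.68°, 8 repetitions,
88 trials).

## Preprocessing

Trial validity is judged *before* interpolation: a record is invalid when
its longest contiguous missing run exceeds 40% of its samples. Interior
gaps are filled by linear interpolation against time; edge gaps stay
invalid. Velocity uses the 5-sample smoothed central difference
`v[i] = (x[i+2]+x[i+1]−x[i−1]−x[i−2])·fs/6`; per-axis thresholds are
`λ·σ` with σ the median-based spread `sqrt(median(v²) − median(v)²)`
(floored at machine scale for noiseless synthetic traces) and λ = 6. A
sample is saccadic when the elliptic criterion `(vx/ηx)² + (vy/ηy)² > 1`
holds; saccadic runs shorter than 12 ms are folded back into fixations.
Fixation refinement merges neighbors separated by < 75 ms and < 0.5°
(duration-weighted centroid), then discards fixations under 60 ms,
repeating both passes to a fixed point so the operation is idempotent.
The numeric defaults are standard published values; the source study's
exact selection parameters live in supplementary material that is not
reproduced here, so all of them are configurable. Thresholds are computed
per record (per trial / per 1-min rest / per image).

## Features and PCA

Twelve features per viewing record: fixation count, mean/total fixation
duration, mean duration in the first and last window (15 s windows for the
1-min blank-screen record; 1.25 s windows for 5-s image viewing), gaze-step
mean/SD/max (Euclidean distances between successive samples), horizontal
and vertical gaze-flip rates (sign inversions of successive per-axis
displacements, zero displacements transparent), mean saccade amplitude,
and saccade rate. The exact published feature list is supplementary-only;
this set covers every feature named in the main text plus the two standard
event statistics, and is configuration-driven. Feature matrices are
z-scored before PCA (correlation-structure PCA — the features have
heterogeneous units), components carry a deterministic sign convention
(largest-magnitude loading positive), and per-image vectors are averaged
per participant. Per-sample flip rates and step statistics at 600 Hz are
dominated by tracker/oculomotor jitter; that is true of the measured
quantity itself, not an artifact of the generator.

## Transfer statistics

The barycenter is the *unweighted* mean horizontal fixation position
(a duration-weighted variant exists but is non-default). Pre-to-post raw
shifts are negated for the left-bias group so positive always means
"toward the trained hemifield"; the three tasks are tested with one-sided
one-sample t-tests (exact noncentral machinery, Cohen's d = mean/SD).
Image-viewing shifts are computed per image and collapsed with the median.
The congruent-bias index is the absolute early-viewing median position,
signed by agreement with the trained side. Density maps are
duration-weighted Gaussian-kernel grids (bandwidth 1°, 0.25° spacing —
unreported in the source, hence defaults), excluding the first 750 ms,
optionally x-flipped to pool groups, combined across target positions by
cellwise median, and renormalized. Alignment of the two free-viewing shift
directions with the trained side is tested with an exact one-sided binomial
test against the 0.25 chance level.

The learning curve bins gaze-target distance as the median over 500-ms
intervals of the live trial span (carry-forward padding to the deadline is
a plotting option only). The learning model is a fixed-effects gamma GLM
with log link on standardized Time-On-Trial and Trial-Number and the
biased/unbiased indicator with all interactions, reported as multiplicative
factors with drop-one likelihood-ratio p-values (dispersion fixed at the
full model's estimate). The published analysis is a random-slopes GLMM;
mixed-model estimation is outside this package's contribution, so the GLM
is the built-in core and a long-format CSV contract (see `gazebias.io`)
lets an external mixed-model engine (e.g. glmmTMB through R) stand in
behind the same coefficient schema.

## Design computations

Power for the one-tailed paired t-test uses the exact noncentral t
distribution (df = n−1, noncentrality d·√n): d = 0.4 at α = .05 gives
92.2% at n = 60 and 79.97% at n = 40 — the printed 92%/80%. Note the
required-n inverse of the *rounded* 80% is 41, not 40. The two-look
group-sequential solver integrates the correlated-look multivariate normal
(correlation √(t_i/t_j)) and reproduces the classical two-sided Pocock
level 0.0294 at K = 2; the study's 0.0329 decision threshold is surfaced
as configuration, not asserted as the solver's output, because the
convention behind it (sidedness, table) is not stated in the source.

## Problem sizes and what the results show

Full-scale simulation (40 participants, 180 trials at 600 Hz, 1-min rest
records, 30 images) runs in well under a minute per cohort; the packaged
tests and the acceptance script use reduced sizes chosen as a deliberate
trade-off (20–24 participants, 90 trials, 150–250 Hz, 40-s rest records).
At these sizes the qualitative signatures are stable across seeds:
within-trial factor ≈ 0.73, across-trial factor ≈ 0.94–0.98, ~90% found,
~4 s mean search, pooled free-viewing shift +0.3 to +0.9°. Statistical
*significance* of the shift on any single desk-scale cohort is not asserted
— the induced effect is deliberately small (d ≈ 0.3, as in the human data,
where it was marginal at n = 40) — so the seeded end-to-end test checks
direction, and test calibration (type-I error ≈ 5%, power monotone in the
induced bias) is verified at the shift-measure level where the statistic
itself is under test.

The generator emulates fixation/saccade alternation, exploration biases,
blinks, loudness-guided search and logistic bisection responses. It does
not emulate image content or saliency, smooth pursuit, main-sequence
saccade dynamics, binocular disparity, calibration drift, or fatigue.
Passing tests therefore show that the analysis chain measures what it
claims on data with known ground truth — not that the human effects would
replicate.

## Known limitations

* The agent policy is one of many consistent with "search guided by scalar
  loudness"; quantitative search-time distributions are not calibration
  targets.
* The fixed-effects GLM understates between-participant heterogeneity
  relative to the published random-slopes GLMM; its factors are not
  numerically comparable to the published coefficients.
* Success-truncation couples trial outcomes to bin availability in the
  learning model (trials end at success, so late bins over-represent
  failures); the same coupling exists in the real design.
* The Hooge-style refinement parameters and the 12-feature list are
  explicit stand-ins for supplementary material and are configurable.
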