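# Methods

This note describes the models and procedures implemented in `gazefatigue`,
the choices made where the design was genuinely open, and what the synthetic
study generator does and does not emulate.

## The assessment method

The package implements an eye-movement based assessment of mental fatigue
for PC operators. A session's raw gaze trace (timestamps plus horizontal and
vertical position in degrees of visual angle) is reduced to oculomotor
events and kinematics, from which a catalogue of 27 named characteristics is
computed. A four-criterion screening step measures how each characteristic
relates to independent fatigue ground truth (the Landolt-rings Au mental
performance index, choice-reaction-time slowing, the VAS-F fatigue scale and
within-session dynamics), and a small selected subset feeds a binary
classifier (fatigued = low mental performance) that can then be applied to
streaming gaze windows.

### Event detection

Fixations are found with a dispersion-threshold (I-DT) scan: a maximal run
of samples is a fixation when its *dispersion* — the maximum pairwise
Euclidean distance, i.e. the diameter of the point set — stays within the
fixation-area diameter *d* and the run lasts at least the minimum fixation
duration (default 50 ms). The scan is greedy left-to-right: grow the window
while dispersion holds; emit and restart past it if long enough, otherwise
slide the start one sample. The "diameter" reading of dispersion (max
pairwise distance rather than the cheaper per-axis extent) is deliberate,
and the diameter is the method's central tunable: characteristics can be
recomputed on a grid of diameters from 0.1° to 2.5°, with 1.0° as the
single-diameter default.

Dispersion-qualified runs of at least two samples that are too short to be
fixations are tallied as *false fixations*; their per-minute rate is itself
a catalogue entry. This definition is an interpretation (the term has no
standard definition) and is configurable.

Saccades are derived, not detected: one per consecutive fixation pair inside
a segment, with amplitude measured centroid-to-centroid and duration as the
inter-fixation interval. Blink and dropout gaps up to 75 ms are linearly
interpolated; longer gaps split the recording into segments that are
processed independently, so no data is fabricated across gaps.

### Kinematics

Instantaneous velocity is |Δposition|/Δt per sample pair; acceleration is
the per-sample difference of the velocity vector. Trajectory curvature is
the Menger curvature of each consecutive sample triplet — the reciprocal of
the circumradius, in 1/deg — chosen because it has an exact analytic oracle
(points on a circle of radius R give exactly 1/R) and degrades gracefully to
0 on collinear triplets. "Second interval" features aggregate over
non-overlapping 1 s bins anchored at the recording start; the modulus of
average acceleration is the norm of the bin-mean acceleration *vector* (so
symmetric oscillation cancels), and the bin minimum velocity is averaged
over bins.

### The characteristic catalogue

27 entries in six groups (velocity-, temporal-, percentage-, quantitative-,
saccade-length- and trajectory-based). Conventions fixed so the algebraic
identities are exact and testable:

* "shorter than T" means duration < T; "longer than T" means ≥ T; "between
  150 and 900 ms" means [0.150, 0.900) — so each <T / ≥T pair sums to 100%
  exactly (the ≥T member is stored as the literal complement).
* Proportion-of-time entries use **total fixation time** as denominator, so
  the three duration bins partition 100%. (Total recording time would be the
  other defensible reading; the partition identity is why this one is the
  default.)
* *Average velocity within the fixation area* is net displacement over
  duration; *average speed in the fixation area* is path length over
  duration. This is the only reading under which the two names denote
  different quantities; the speed variant is the expert-added 27th entry.
* Per-recording values are event-weighted means over events (fixations,
  saccades, triplets, 1 s bins), not time-weighted.
* Undefined entries (no saccades, no fixations) are explicit absences.

Per-feature summary statistics (mean, SD with n−1, min, max, and the
quartiles by linear interpolation) expand any feature time series into seven
values; the "coordinates" feature set is these seven statistics of the raw
x, y and velocity series.

### Relevance screening

Per characteristic, four criteria:

1. **Wilcoxon** two-sided rank-sum p comparing sessions with high vs low
   mental performance (Au ≥ 1.5 vs < 1.5). Exact null distribution for
   combined n ≤ 25 without ties, tie-corrected normal approximation
   otherwise; all-tied data gives p = 1.
2. **Inner-session dynamics**: share of sessions where the characteristic
   rose from the first to the last block of the session, share where it
   fell, and the larger of the two. Blocks default to the first and last
   10 % of the recording, standing in for the reaction-time task epochs that
   open and close a session.
3. **CRT**: Spearman correlation (Pearson selectable) between session-level
   characteristic values and the post-minus-pre mean reaction time, per
   fixation-area diameter on the grid; the signed correlation of maximal
   magnitude and its argmax diameter are kept.
4. **VAS-F**: the same max-over-diameters correlation against the
   pre-session fatigue score.

Selection filters at raw p < α (no multiplicity correction by design — the
screening is deliberately liberal; Benjamini–Hochberg is available but off),
ranks by p, then dynamics score, then |CRT correlation|, then catalogue
order, and unions the first `head_size` *non-expert* candidates with the
configured expert additions. Excluding additions from the head keeps the
selected-set size at `head_size + additions` regardless of how well the
additions screen. Head size and additions are configuration because the
expert step is judgment, not computation.

### Classification

Preprocessing: quasi-constant removal (modal relative frequency ≥ 0.99),
z-score normalization (population-SD convention, which makes the transform
idempotent), greedy removal of columns with |Kendall τ| ≥ 0.9 against an
already-kept column, PCA to 95 % kept variance. All steps are one sklearn
`Pipeline`, so cross-validation refits them inside each fold and a saved
model transforms future windows identically.

The model grid spans six families with fixed hyperparameter lists (random
forest: 10–100 trees × {gini, entropy, log_loss}; decision tree: 3
criteria; k-NN: k = 1..10 × {uniform, distance}; MLP: 3 solvers × 4
activations × hidden sizes 1..20, log-loss; logistic regression: 5 solvers,
log-loss; SVM: 4 kernels, hinge loss). Each configuration is evaluated on a
random split holding out a fixed per-class test count *and* under stratified
10-fold CV; the best configuration is the one with the highest random-split
accuracy, with F1 (positive class = fatigued) reported alongside. Streaming
assessment slides a 60 s window in 1 s steps, recomputes the model's exact
feature definition per window, and reports an explicit "insufficient data"
status before the first full window.

## The synthetic study generator

The generator stands in for a longitudinal operator study (by default 15
participants × 7 days × 3 sessions) whose real recordings are not available.
It emulates, per recording:

* alternating fixation epochs and saccades on a uniform 100 Hz grid
  (configurable — source studies rarely report tracker rates);
* fixation durations from a three-component log-normal mixture (short
  ≈ 85 ms, regular ≈ 300 ms, long tail ≈ 1.3 s) so all duration bins are
  populated;
* within-fixation drift along a small circle (radius 0.15°) with a random
  angular rate direction — bounded drift guarantees long fixations are never
  chopped by the dispersion window;
* elliptically polarized physiological tremor (major axis 0.12°, minor
  0.06°, ≈ 37 Hz): the fixed minor axis bounds the sampled second difference
  away from zero, so near-collinear triplets cannot arise by chance inside
  fixations, and it pins the per-bin velocity floor;
* AR(1) measurement noise (SD 0.015°) on every sample;
* saccade amplitudes as a hard floor (2°) plus an exponential excess (mean
  amplitude 5°), a minimum-jerk displacement profile whose peak velocity
  obeys the main sequence (peak = slope × amplitude, slope 40 /s), a
  parabolic sideways bow (constant curvature ≈ 8c/A), and tracker-style
  endpoint snapping: reported gaze sticks to the flanking fixation until the
  eye is 1.8° clear of it. Snapping emulates tracker smoothing/latency and,
  importantly, prevents mid-flight samples from sitting just inside a
  fixation window's dispersion budget, which would otherwise split fixations
  and litter the event stream with sub-degree artifact saccades;
* blinks as gaps of invalid samples (10/min, 150 ms), never zero
  coordinates;
* multiplicative log-normal between-session jitter on drift, noise,
  duration and amplitude parameters — the biological and instrumental
  heterogeneity that makes equally fatigued sessions non-identical.

### The fatigue model

Fatigue is a level in [0, 1]; each affected parameter is scaled by
`multiplier ** level` (monotone by construction). Sessions ramp from their
scheduled level to that level plus 0.25–0.4 within the session, which is
what the inner-session dynamics and the CRT delta read out. Ground truth is
linear in the level with additive Gaussian noise: Au falls from 3.0 to 0.0
(crossing the 1.5 dichotomy at level 0.5; noise SD 0.15 so the dichotomy is
reliable at full contrast), CRT mean RT rises 0.45→0.70 s, VAS-F fatigue
rises 2→8 of 10. A zero-noise mode makes ground truth deterministic.

The default effect configuration targets the seven selected
characteristics, each through its own mechanism: drift speed falls (average
velocity within the fixation area), the tremor major axis falls (average
trajectory curvature rises — discrete curvature scales inversely with the
sample step), saccade bowing grows (minimum curvature rises), the amplitude
floor falls at constant mean (minimum saccade length falls, average length
stable), and the short-fixation component slides from ≈ 85 ms to just under
the 180 ms line while mass moves from the regular component into the long
tail (the share of, and time spent in, sub-150 ms fixations collapse while
the quasi-complementary 150–900 ms band roughly balances). The balancing
lever and the session jitter exist because duration-bin features are linked
by conservation: any mass leaving one bin lands in another, and without
compensation the screening would flag the receiving bins as strongly as the
planted ones.

Known limitation: the *minimum* trajectory curvature is only weakly
plantable. The session minimum over ~10⁴ triplets is an extreme statistic
whose lower tail is dominated by chance near-collinear triplets where a
small step neighbours a large saccade step; its distribution is heavy at
zero in both fatigued and rested sessions, so its group separation
fluctuates seed to seed. The selection experiment still recovers six of the
seven targets in ≥ 18/20 seeds because the remaining characteristics and
the expert addition carry the selection.

### What passing tests do and do not show

The generator produces stationary-statistics sessions with independent
sessions, Gaussian-mixture event parameters and an idealized main sequence.
Real gaze data has non-stationary task structure, smooth pursuit, vergence
and calibration drift, correlated ground-truth instruments, and
participant-level random effects none of which are modelled. Passing the
recovery and classification checks therefore shows the *pipeline* is
correct and calibrated (type-I error at nominal level on null studies,
planted effects recovered at realistic magnitudes) — not that the selected
characteristics or accuracy would transfer to any particular real
population.

## Problem sizes

Monte-Carlo experiments use scaled-down studies chosen to keep the full
suite in the minutes range while preserving the protocol's shape: screening
calibration on 10 × 3 × 30 s null studies (20 seeds); planted-effect
recovery on 14 participants × 2 sessions (rested vs sub-maximal fatigue
0.6) × 120 s with a single-diameter correlation grid (20 seeds);
classification on 15 × 2 × 100 s studies split into 7 windows per session
(≈ 210 samples, 50 + 50 balanced test, full random-forest grid, 10-fold
stratified CV, 10 seeds); chance-level control on 3 null studies. The
full-size 15 × 7 × 3 design is exercised for counting and determinism
with short sessions.

## Numerical conventions

Timestamps are seconds (floats), 0-based sample indexing; gaze files are
`t,x,y[,valid]` CSV with units and screen geometry in a YAML sidecar;
pixel-to-degree conversion is per-axis `atan(offset/distance)` about the
screen centre (exact at wide angles, invertible to 1e-9). Dispersion uses
exact pairwise distances; curvature of degenerate (repeated-point or
collinear) triplets is 0. Percentile interpolation is linear; normalization
uses population SD; all randomness flows from explicit integer seeds
(`numpy.random.default_rng`), and every stage is bit-reproducible given the
seed.
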