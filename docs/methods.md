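# Methods

`zfsleep` implements the quantitative pipeline used for larval zebrafish
sleep phenotyping: videotracker sleep scoring, mechano-acoustic
arousal-threshold psychometrics, trial-structured calcium-imaging
quantification with PCA/ICA neuron segmentation, and the group statistics
used to compare genotypes and treatments. A synthetic-data layer generates
every data type with known ground truth, so the whole pipeline is testable
without recordings.

## Sleep scoring model

Activity is seconds of movement per 1-minute bin, recorded per well of a
96-well plate at 15 Hz and binned by the tracker. The operational
definitions are:

- **Movement event** — a run of nonzero inter-frame pixel displacement
  preceded and followed by at least 67 ms of stillness. At 15 Hz one
  inter-frame gap is 66.7 ms < 67 ms, so a single still frame does *not*
  separate two events; two still frames (133 ms) do. This boundary is
  declared explicitly because the frame rate and the gap threshold straddle
  each other.
- **Sleep minute** — a 1-minute bin with no movement. Numerically, activity
  ≤ 1e-9 s counts as zero (exact zero up to float noise).
- **Sleep bout** — a maximal run of consecutive sleep minutes
  (half-open `[start, end)` intervals).
- **Sleep latency** — minutes from a reference event (lights on/off, or
  heat-shock onset) to the start of the first sleep bout. A bout already
  ongoing at the reference gives latency 0. If no bout occurs before the
  epoch ends, the latency is reported as the remaining epoch length and
  flagged *censored* rather than dropped, which avoids survivorship bias in
  group means. Whether post-heat-shock latency is referenced to the onset or
  the end of the heat pulse is the caller's choice of reference time.
- **Average activity** — 60 × mean seconds-of-movement per minute (s/h),
  including sleep minutes; **wake activity** excludes sleep minutes and is
  NaN when the animal never woke. Wake activity ≥ average activity whenever
  at least one sleep minute exists.
- **Epoch metrics** — day/night epochs come from a light schedule
  (default 14:10 with lights on at 9 h and off at 23 h; the 13:11 imaging
  schedule is expressible the same way). Bouts spanning an epoch boundary
  are split at the boundary for per-epoch sleep totals (splitting conserves
  total sleep) and count once in each epoch they touch. Light transitions
  snap to minute-bin boundaries anchored at recording start.
- **Trend smoothing** — a centered 6-point moving mean on 10-min binned
  series (1-h window), shrinking to the available points at the edges. For
  the even window the covered offsets are [−3, +2].
- **Percent-of-control** — 100 × value / mean(control), i.e. a ratio to the
  control-group mean rather than a mean of per-animal ratios. The light-pulse
  response divides each animal's pulse-period activity total (excluding the
  minute after light onset) by the group-mean baseline total over the
  matching 30-min pre-pulse window (excluding the minute before onset), so a
  genotype with unchanged behavior scores exactly 1.

## Arousal-threshold psychometrics

Tap stimuli span a 0.01–40.95 power scale; the standard design uses 14
log-spaced intensities between 1 and 36.31, 30 trials each (420 trials per
larva), in randomized order. Per-power response fractions are corrected by
subtracting the group's background movement probability (the fraction of
trials with movement in the 5 s before a stimulus), floored at 0 because
fractions are probabilities.

Corrected fractions are fit by unweighted least squares (optional weights
exposed) with the variable-slope log-dose model

    y(x) = bottom + (top − bottom) / (1 + 10^((log10(ETP50) − log10(x))·hill))

with bounds bottom ≥ 0, top ≤ 1, hill unconstrained in sign. Initialization
is data-driven (plateaus from the data extremes, midpoint from the power
closest to half-range, hill = 1) plus eight deterministically seeded jittered
restarts; the lowest residual sum of squares wins. Constant fractions yield a
flagged degenerate fit with undefined ETP50. The fitted ETP50 (the power at
the half-maximal response) is equivariant under rescaling of the power axis.

Two groups are compared with the extra-sum-of-squares F test on nested fits:
the null model shares all four parameters; the alternative shares bottom, top
and hill and frees log10(ETP50) per group. Hence df1 = 1 and
df2 = n_points − 5, with n_points the number of fitted response-fraction
points. F = ((SS_null − SS_alt)/1) / (SS_alt/df2), p from the F distribution;
an (essentially) zero SS_alt is reported as a perfect fit with a
machine-floor p-value.

Calibration: with homoscedastic Gaussian errors around a common curve the
test's type-I error is at its nominal level (the test suite verifies 0.05
within binomial confidence bounds over 500 null replicates, and uniformity of
the null p-values). Applied directly to per-power *binomial* response
fractions the unweighted test is mildly anti-conservative, because binomial
variance varies across the curve; this is a property of unweighted
least-squares fitting of fractions, not of the F statistic, and binomial
weighting is available for users who want it.

Percent changes between ETP50s are reported as
`trunc(100·(treated − reference)/reference)` — truncation toward zero is the
reporting convention and reproduces the reference values 227, −46 and −65
used in the tests.

## Calcium-imaging quantification

Trials are 120 samples at 1 Hz: intrinsic activity up to 31 s, light on at
t = 32 s, light off at t = 93 s. Window statistics use inclusive
integer-second windows — 5–25 s (intrinsic, 21 samples), 32–37 s (on-evoked)
and 93–98 s (off-evoked); inclusivity is a declared convention. Per-trial
series are smoothed with a centered 5-trial moving window (shrunk at the
edges), and the post-stimulation steady state is the mean of trials 10–15
(1-based, the last six of a 15-trial session).

Baseline (F0) conventions: the global minimum of the recording (ΔF then has
minimum exactly 0); the mean of the first five trials (optogenetic
stimulation sessions); or the minimum of the trace after a centered 5-s
boxcar smooth (the per-neuron rule). Normalization constants (F_N): the mean
intrinsic activity during subjective day, the per-animal peak after light
onset (normalized post-light maximum is then exactly 1), or the per-animal
day mean. Day/night summaries average the two day periods flanking a night;
the night/day ratio is taken per animal, so the normalized day value is 1 by
construction and genotype comparisons at night are made on per-animal
normalized values.

### PCA/ICA segmentation

The movie's pixel-time matrix is mean-subtracted (making the output
invariant to constant intensity offsets) and reduced by PCA — 15 components
by default, or however many reach an explained-variance target when one is
given; the retained explained-variance ratios are reported and match the
covariance eigenvalue ratios. FastICA then unmixes the retained spatial
eigenmaps into independent spatial filters (pixels as samples). Each filter
is sign-fixed to positive skewness; filters whose skewness stays below 1.0
are discarded as noise (on synthetic movies, noise-only maps have |skew|
< 0.1 while cell-bearing maps exceed 5, so the gate is far from both
populations). Surviving maps are smoothed with a Gaussian of
``spatial_filter_px/6`` and thresholded at mean + 3.5 SD; each
supra-threshold region is refined to the connected blob above half its peak
(FWHM-style), kept if the blob's equivalent diameter lies within
[0.5, 2] × the expected cell diameter, and deduplicated across filters by
centroid distance (0.75 × diameter). ROI traces are the mean movie intensity
over each mask, with the smoothed-minimum baseline. Higher-order components
are cut by the count/variance rule rather than by visual inspection — a
deliberate, documented divergence from manual practice.

## Group statistics

Student's two-tailed t-test uses the pooled-variance form by default (Welch
available); zero-variance samples with equal means give t = 0, p = 1 by
convention. One-way ANOVA is computed from textbook sums of squares and
reproduces t² exactly with two groups. Two-way ANOVA (statsmodels) assumes
near-balanced designs as produced by plate layouts; unbalanced input warns
and uses Type-II sums of squares. Holm-Sidak adjustment is the step-down
closed form `1 − (1 − p_(i))^(m − i + 1)` with a running maximum. Dunnett's
many-to-one comparisons use SciPy's implementation of the max-|t| null
distribution under the Dunnett correlation structure; the suite verifies
familywise error ≈ 0.05 under a simulated 7-treatment global null. Relative
qPCR expression uses ΔΔCt with the calibrator chosen per gene as the sample
with the highest target Ct (lowest expression = 1.0), so the calibrator's
relative expression is exactly 1.

## Synthetic data generators

The generators define the study conditions the tests run under:

- **Behavior** — a two-state (wake/sleep) Markov chain per minute with
  epoch-specific transition probabilities. Defaults: 48 larvae/group; wild
  type p(wake→sleep) = 0.01/min by day and 0.07/min by night,
  p(sleep→wake) = 0.25/min by day and 0.10/min by night, giving the diurnal
  pattern (little day sleep, ~40% night sleep) typical of larvae. Wake-minute
  activity is gamma (shape 2, scale 3 s; mean 6 s/min) truncated to
  [0, 60] s and scaled by a per-group multiplier — the distribution itself is
  a modeling choice: positive and right-skewed like real actigraphy. Sleep
  minutes are exactly 0. Heat-shock effects multiply the transition
  probabilities from heat-shock onset with an exponentially decaying factor
  (half-life 3 h by default), emulating decaying overexpression of an
  induced transgene; the default transgenic preset (wake→sleep ×27,
  sleep→wake ×0.83, activity ×0.38) reproduces the qualitative
  phenotype — minutes-scale sleep latency after induction, more and slightly
  longer sleep bouts, reduced wake activity. Sleep-bout lengths are
  geometric with mean 1/p(sleep→wake) by construction, and the stationary
  sleep fraction is p_ws/(p_ws+p_sw); both are verified against the scorer.
- **Taps** — responded ~ Bernoulli(ψ(power) + bg·(1 − ψ(power))): the
  psychometric response OR background movement, consistent with analyzing
  background-subtracted fractions. Defaults: bottom 0, top 0.95, ETP50 6.2,
  hill 1.8, background 0.07, 14 × 30 design.
- **Calcium trials** — 120-sample traces with a phase-dependent baseline
  (day 100, night 75 counts → a planted 25% night suppression), a flat
  on-transient over 32–37 s (amplitude 40), exponential habituation
  (τ = 20 s), a flat off-transient over 93–98 s (amplitude 30), and Gaussian
  noise (SD 2). The flat-transient kernel makes the on-window mean minus the
  intrinsic mean equal the configured amplitude exactly at zero noise, which
  pins the generator to the window convention. A suppression mode decays the
  per-trial baseline toward a night-like level after the stimulation-onset
  trial.
- **Movies** — Gaussian-profile nuclei of FWHM 5 px (pixels stand in for the
  ~5 µm nuclear diameter) at centroids ≥ 10 px apart, each with an
  independent Bernoulli-spike train (0.05/frame, at least one spike)
  convolved with an 8-frame exponential decay, amplitude 50 on background 10
  with noise SD 0.5. Ground-truth masks are the half-max (FWHM) disks.
  Segmentation benchmarks run on 64×64×200 movies with 20 planted cells, not
  full-brain frames.

RNG discipline: all draws use NumPy `default_rng` (PCG64). Each larva owns a
stream seeded by `(seed, group_index, larva_index)`; trial and movie
generators use `(seed, constant, offset)` streams. A fixed seed therefore
gives byte-identical datasets, and adding animals never perturbs existing
ones.

### What the generators do and do not emulate

They reproduce the *statistical structure* the analysis consumes: diurnal
two-state behavior with configurable effect sizes, background-contaminated
psychometric responses, phase- and stimulus-locked fluorescence, compact
active cells on noisy background. They do not emulate raw video, tracker
device units (detection/burst/freeze thresholds), drug pharmacokinetics,
circadian drift, inter-animal correlation within a plate, movement artifacts,
or overlapping/out-of-focus cells. Passing round-trip tests therefore shows
the estimators are correct and calibrated under the stated model, not that
the model captures every feature of real recordings.

## Numerical choices and limitations

- Least-squares fits use `scipy.optimize.least_squares` (TRF) with
  xtol = ftol = gtol = 1e-14; noiseless curves are recovered to ~1e-8
  relative error. Multi-start ties are broken by first-found.
- If a fit converges with bottom > top it is re-expressed in the equivalent
  parameterization (plateaus swapped, hill negated).
- Degenerate inputs fail loudly: constant movies, zero-variance correlation
  inputs, empty displacement series, non-positive powers and divisors all
  raise `ValueError` rather than returning silent NaNs (wake activity with no
  wake minutes is the one flagged NaN, by definition).
- The per-minute Markov simulation is a Python loop (state-dependent), fast
  enough for ~2×10^5-minute traces used in the goodness-of-fit tests; test
  and acceptance problem sizes (48 larvae/group, 64×64×200 movies, a few
  hundred Monte-Carlo replicates) were chosen so the whole suite runs in a
  few minutes on one core.
- Dunnett p-values come from SciPy's numerical multivariate-t integration and
  are reproducible only to ~1e-4; tests compare them at that tolerance.
- The extra-SS comparison shares bottom/top/hill between groups. If the true
  curves differ in slope or plateaus, the shared-parameter alternative is
  misspecified and the test answers "do the midpoints differ given a common
  shape", which is the intended question here.
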