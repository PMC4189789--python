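# Methods

## Fourier readout of periodic intrinsic signals

The imaging analysis assumes a periodic stimulus whose repetition frequency
`f_stim = 1/repetition_period` (0.05 Hz for the 20 s default) falls exactly
on a DFT bin of the recorded stack — i.e. the stack spans a whole number of
stimulus periods.  Under that condition the DFT bins are orthogonal, so the
estimate of the stimulus-frequency component is unbiased by any nuisance
signal confined to other bins (drift, respiration, heartbeat), and a
noiseless single-tone pixel is recovered to machine precision.  A stack that
violates the condition is rejected rather than analysed, because spectral
leakage would bias every magnitude silently.  The readout for a pixel with
series `x_t` and temporal mean `m` is

    magnitude = 2 |X(f_stim)| / (n m),    phase = arg X(f_stim)

with `X` the DFT of the mean-subtracted series.  The `2/n` factor converts a
one-sided DFT coefficient to sinusoid amplitude; dividing by the pixel's own
mean makes the result the dimensionless fractional reflectance change ΔR/R,
the standard normalisation for reflectance imaging (the protocol does not
fix one, so per-pixel mean normalisation is a design choice here).
Detrending is mean subtraction only by default — a nonzero bin is already
insensitive to offsets — with an optional linear detrend for ramp-y
recordings.  Pixels with non-positive mean cannot be normalised; they are
flagged NaN and excluded from threshold counts.  The whole 35-repeat series
is analysed as one continuous record; there is no per-cycle averaging.

The complete time series is analysed at full length; spatial binning
(block-averaging, `spatial_bin`) is available and commutes with the readout
over regions of constant amplitude.

### Threshold curves and the genotype comparison

The responsive region is summarised as the number of pixels with magnitude
strictly greater than each threshold of an ascending grid.  No
region-growing or vessel masking is applied: the "region of response" is the
full field, optionally restricted by a caller-supplied ROI mask.  The
default grid is 10 evenly spaced values between the 50th and 99.5th
percentiles of the pooled finite magnitudes, shared across all animals in a
comparison (the in-vivo grid for this figure is not published, so the
package's grid is its own convention and is configurable).  Counts at every
threshold for every animal enter an ordinary two-way ANOVA
(genotype × threshold, type-II sums of squares, via statsmodels); the
genotype main effect is the headline number.

## The imaging phantom

Each pixel is `B (1 + A_rc w(t))` plus additive nuisances, where
`A_rc = peak_drr · exp(−d²/(2σ²))` is a Gaussian-profiled amplitude map and
`w` is a unit cosine at the stimulus frequency.  Defaults: 64×64 pixels,
700 frames at 1 frame/s (35 cycles of the 20 s period compressed to desk
scale — only frequency ratios matter to the analysis), baseline 1000 camera
units, peak ΔR/R 1e-3, white noise SD 2, drift one cycle per record
(amplitude 5), and confound tones on bins 7× and 9× the stimulus bin (0.35
and 0.45 Hz; surrogates for respiration- and heartbeat-band contamination —
both on exact non-stimulus bins so the ground truth stays analytic; a
30×-style confound does not fit below Nyquist at the compressed default
geometry, so the defaults stay within it).  Because every nuisance is
orthogonal to the stimulus bin, the returned ground-truth map is exact for
the noiseless phantom, which is what makes the 1e-10-level recovery checks
meaningful.  A `boxcar` waveform mode (15% duty, matching a 3 s train per
20 s period) is available for more realistic time courses; its ground truth
uses the Dirichlet-kernel fundamental of the tiled boxcar and accounts for
the small mean shift the on-phase adds to the normalising baseline.  The
pure-tone mode is the tested default because it makes truth exact rather
than approximate.

What the phantom does *not* model: hemodynamic response shapes and delays,
vessel artefacts, spatial correlation of noise, photobleaching, and motion.
Passing recovery tests therefore demonstrates correctness of the spectral
readout, not robustness to every in-vivo artefact.

### Noisy-recovery check

With white noise, the magnitude estimator is Rician: strictly positively
biased wherever the true amplitude is near zero, so no per-pixel band on the
*magnitude* mean can hold at background pixels.  The recovery check instead
projects the recovered complex coefficient onto the known phantom phase
(`magnitude·cos(phase)`, unbiased Gaussian), and requires the mean over 100
seeds to sit within 4 standard errors of truth at every pixel of a 16×16
phantom — 4 SE rather than 2 because the check is joint over 256 pixels (a
2 SE per-pixel band would fail with near certainty for any unbiased
estimator; at 4 SE the joint false-alarm probability is ≈ 1.6%).

## The behavioral agent

Success at gap distance `d` (cm) in session `s` (1..12) is Bernoulli with

    p = (1 − lapse) · logistic(intercept − slope·d + L(d)·(s − 1))

where `L(d)` is the nose-class learning rate for `d ≤ 4.5` cm and the
whisker-class rate above.  Learning linear in logit space per session is the
simplest monotone model that produces block-wise improvement; the lapse rate
caps asymptotic performance below 100%.

Defaults (the simulated study conditions): `intercept 4.0`, `slope 1.0/cm`,
learning rates 0.2 logit/session, `lapse 0.02`.  These were chosen once so
that the cohort reproduces the qualitative structure of the real assay:
initial success high at short gaps (~73% at 3.0 cm) and declining with
distance (~12% at 6.0 cm in session 1), both classes improving by roughly
15–25 percentage points between session blocks when learning is present.
The knockout condition zeroes the whisker-class rate only, expressing a
deficit specific to whisker-dependent distances while nose-distance learning
and overall task engagement stay normal.  Simulated knockouts are not
fitted to any animal; they encode the qualitative hypothesis, so simulation
results validate the pipeline, not the biology.

Trials also carry a sensor-event trace (1 = home rear, 2 = home edge,
3 = target edge, 4 = target rear): successes run 1→2→3→4; failures retreat
either from the home edge (1→2→1) or after touching the target edge
(1→2→3→2→1), both shapes with equal probability.  Trial duration is
`crossing_time·U(0.75, 1.25)` for both outcomes; the adjustment phase
between trials is `max(0, N(inter_trial_mean, inter_trial_jitter²))`
seconds.  Defaults (8 s crossing, 20 ± 5 s adjustment) give ~35–40 trials in
a 20-minute session, so sessions end by quota when performance is high and
by timeout otherwise.

## The closed-loop engine

Exploration and adjustment alternate.  Every session starts at 3.0 cm; after
each trial the next distance is drawn uniformly from the 0.5 cm grid between
`max_crossed − 1.0` and `max_crossed + 1.5` cm, clamped to [3.0, 7.0].
Decisions the protocol leaves open, resolved as follows:

- *Before the first success of a session* the maximum crossed distance is
  undefined; the engine anchors the window at the starting distance
  (3.0 cm), giving the early-session candidate set {3.0 … 4.5}.  This is
  consistent with every session starting at 3.0 cm.
- *`max_crossed` updates only on successes* ("crossed" is read as a
  successful crossing); a failure at a long distance does not move the
  window.
- *Timeout is checked between trials*: a trial in progress when the
  20-minute clock expires completes and is recorded.
- Distances are held as integer half-centimetre units internally; exact grid
  membership is load-bearing for the adaptive rule, so no floating-point
  arithmetic touches it.

Trial outcomes are re-derived from the sensor trace by the engine
(`classify_trial`) rather than trusted from the agent, so a malformed trace
aborts the session with a diagnostic; the same classifier drives replay
validation of serialized logs.

## Learning statistics

Success tables count trials and successes per (mouse, session, distance).
Analysis restricts to 3.0–6.0 cm (the engine can emit 6.5/7.0 cm trials;
they are excluded from scoring), split into nose (3.0–4.5) and whisker
(5.0–6.0) classes.  4.5 cm is a boundary case: it is assigned to the nose
class by default so the classes exhaust the analysed range, and
`distance_classes(nose_includes_4p5=False)` gives the three-distance nose
class under which six mice yield the (1, 15) error df quoted for this assay.

Block rates pool trials across each block's six sessions
(`100·Σsucc/Σtrials`) by default — robust to sessions that offer a distance
only a few times under the adaptive rule — with per-session averaging
available via `pool="per_session"`.  A (mouse, distance, block) cell with no
trials is missing: it is excluded from that mouse's class improvement, and
the RM-ANOVA drops such a distance listwise (with a warning), refusing only
if fewer than two mice or two complete distances remain.

The RM-ANOVA is a balanced two-way within-subject decomposition computed
in-package (grand mean, block, subject×block, and three-way residual sums of
squares).  The block effect is tested against the *pooled* within-subject
error (block×subject + block×distance×subject), df `(n−1)·k` — the
convention matching published F ratios for this design; the conventional
unpooled test (block×subject error, df `n−1`) is returned alongside and is
cross-checked against pingouin in the test suite.  No sphericity correction
is applied by default (none is used in the published convention this
follows).  Degenerate inputs (all rates equal) return F = 0, p = 1 rather
than 0/0.  Simulation shows the pooled test is well calibrated on
engine-generated cohorts (type-I rate ≈ 0.05–0.06 at α = 0.05 over 1000
no-learning replicates).

Improvement is compared between genotypes with Student's two-sample
two-tailed t test (equal variances assumed; the published analysis does not
state a Welch correction).  Identical zero-variance groups return t = 0,
p = 1.  Cohort totals (per-mouse trials and successes, mean ± SEM per
genotype) serve as the mobility/motivation control.

## Problem sizes

Simulation scales are the package's own choices for desk-scale work:
phantoms 16×16×200 for recovery studies and 48×48×240 for the imaging
cohort (12 stimulus cycles; the analysis consumes frequency ratios, not
durations); calibration studies use 1000 no-learning cohorts of 6+6 mice and
200 pattern-replicate cohorts of 6 WT + 9 KO mice, each mouse 12 full
closed-loop sessions.

## Known limitations

- The phantom's noise is white and spatially independent; real OIS noise is
  correlated and signal-dependent.
- The agent's learning is deterministic in rate and identical across mice of
  a genotype; there is no per-animal random effect, so between-mouse
  variance comes only from binomial sampling and the adaptive schedule.
  Real cohorts are overdispersed relative to this.
- The RM-ANOVA operates on percentages from unequal trial counts without
  weighting; with quota/timeout sessions the counts are similar enough that
  this is immaterial in simulation, but heavily unbalanced real logs may
  warrant a weighted or mixed-effects analysis, which is out of scope.
- Hardware control (motors, doors, feeders, IR sensors) is outside the
  package; the engine runs against the event interface only.
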