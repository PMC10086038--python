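# Methods

## The analysis in brief

Per participant, three conditions are reduced to saccade-locked evoked
combined planar gradients on the window [−0.6, 0] s before saccade onset:

1. **Epoching.** Continuous sensor data are notch-filtered (least-squares
   sinusoid regression at 50/100/150 Hz), cut into epochs around the first
   stimulus onset (photodiode-timed where a stimulus is present),
   downsampled to 500 Hz with a zero-phase FIR anti-alias filter (cutoff
   0.4 × target rate), and screened by the trial rules below. Saccade
   conditions are then relocked so the saccade-onset sample sits at t = 0.
2. **Evoked combined gradients.** Trials are averaged per gradiometer
   channel; each site's orthogonal pair is combined by root-sum-of-squares
   (the conventional magnitude for planar gradiometer pairs); the mean over
   the [−0.6, −0.5) s baseline is subtracted per site. No temporal filter
   is applied before or after this step.
3. **Condition-template GLM.** Per site, the Saccade+stimulus trace Y is
   regressed on the Saccade-only and Stimulus-only traces by ordinary least
   squares over the 301 window samples, without an intercept (all traces
   are baseline-corrected; an `intercept` flag exists for sensitivity
   analyses). The residual ε = Y − β̂·X is the quantity of interest.
4. **Surrogate onsets.** Stimulus-only trials have no saccade, so each
   trial receives `n_draws` surrogate onsets sampled from a Gaussian-kernel
   density estimate of the participant's Saccade+stimulus latencies,
   matched on the trial's stimulus features (orientation × spatial
   frequency × phase, eight cells; cells with fewer than five latencies
   fall back to the participant's pooled distribution). Iteration k relocks
   every trial at its k-th onset, rebuilds the evoked gradient, solves the
   GLM, and the element-wise median over iterations is the participant's
   residual statistic (median, not mean, for robustness to extreme draws).
5. **Group statistics.** Participant residual maps are tested against zero
   with one-sample t-tests, cluster-corrected in space and time: the
   cluster-forming threshold is the two-tailed parametric critical t at
   α = 0.05 (df = n−1), clusters are connected components under sensor
   adjacency (layout distance < neighbour radius) × temporal contiguity,
   separately for positive and negative deviations, cluster mass is the
   summed t, and the null is the maximum |mass| over random participant
   sign flips, p = (1 + #{null ≥ observed}) / (1 + n_perm); on ≤ ~16
   participants an exact mode enumerates all 2^n flips. Sensors with a
   significant run spanning ≥ 12.5 ms — span convention (n_run − 1)/f_s,
   the n/f_s reading is flag-selectable — form the duration mask.
   Lateralization is assessed as the per-participant left-minus-right
   median residual trace (cluster test over time), repeated for occipital
   and parietal site groups; R² and β maps are compared between hemispheres
   with paired t-tests on hemisphere medians; significant-sensor counts per
   pre-saccadic window ([−112, −50] and [−50, 0] ms) are compared with
   Pearson chi-square (Bonferroni factor 2 across the two windows) and an
   independent-binomial Bayes factor with Beta(1, 1) priors computed by
   numerical integration (BF10 < 1 favours equal proportions).

### Trial-inclusion rules

Saccade conditions: exactly one (macro)saccade between stimulus onset and
the second-stimulus onset; endpoint at least 4° past the vertical midline
on the far side; endpoint no lower than 2° below the horizontal midline;
latency within [0.150, 0.500] s, bounds inclusive (boundary trials are
flagged in the metadata so the convention is auditable). Fixation
conditions: gaze within 2° of the fixation point over the entire epoch, and
no saccadic event larger than 0.5° (the 0.5° bound is classified as a
microsaccade, i.e. inclusive, since only events *larger* than 0.5° reject a
trial). Every selector returns a rejection log with exactly one reason per
rejected trial; retained + rejected = input.

## Saccade detection

An adaptive velocity-threshold detector: gaze velocity from Savitzky-Golay
differentiation (order 2, 10 ms window); peak threshold PT by fixed-point
iteration PT ← mean + 6·sd over sub-threshold samples from PT₀ = 100°/s
until the update is below 1°/s (monotone decreasing, capped at 100
iterations); onset/offset thresholds at mean + 3·sd; events closer than the
40 ms minimum fixation duration merged; events shorter than 10 ms
discarded; invalid samples expanded by 50 ms and excluded from threshold
estimation. The smoothing window and the edge rule were set by a simulation
study (500 scripted main-sequence saccades of 1–14° at 0.01–0.02° RMS
tracker noise): a 20 ms window with refinement to the local velocity
minimum — a common textbook choice — biased onsets ~8 ms early, because
the long window smears the velocity profile and the minimum walk descends
into the fixation noise floor; a 10 ms window, stopping at the first
sub-threshold sample, keeps the median onset error ≤ 1 ms and the maximum
at 3 ms with no misses or false alarms. Events at or below 0.5° amplitude
are classified as microsaccades.

Clock alignment: the eye-tracker stream in the acquisition file lags the
sensor clock by 7 ms (digital-to-analog conversion); the generator
reproduces this lag and `align_clocks` shifts the gaze samples 7 ms back.

## The synthetic-data generator

Sessions emulate a three-condition design: fixation at +7° from the screen
midline; on saccade trials a target appears 14° to the left, simultaneous
(on two-thirds of them) with a grating 6° below the horizontal meridian in
the left hemifield; latencies in [0.15, 0.5] s. Defaults: 416/208/208
trials (Saccade+stimulus / Saccade-only / Stimulus-only), 1000 Hz, 102
combined-gradiometer sites.

Evoked components are specified directly at sensor level (no head model):
each has a time course locked to stimulus or saccade onset, a Gaussian
spatial profile on the helmet plane, and a lateralization mode in which
weights are strictly zero outside the active hemisphere. Defaults, chosen
to be physiologically plausible rather than estimated from any dataset:

- *saccade kernel*: biphasic gamma-difference peaking 30 ms after saccade
  onset with a slow pre-movement build-up from −350 ms (so the Saccade-only
  regressor carries energy inside the pre-saccadic window); bilateral,
  fronto-central.
- *stimulus kernel*: non-negative gamma peaking 120 ms post stimulus onset;
  right-lateralized (left-hemifield stimulus), occipital.
- *residual kernel*: half-Hanning ramp rising over the final 112 ms before
  saccade onset; bilateral, occipito-parietal; amplitude 0.4 of the
  stimulus-kernel peak by default, 0 for null sessions. This is the planted
  effect the analysis is supposed to recover.

The per-site amplitude A(t) is split over the gradiometer pair as
(A·cosθ, A·sinθ) with a fixed per-site angle, so root-sum-of-squares
combination recovers |A(t)| exactly (tolerance 1e-10 in the tests). Noise
is white Gaussian (sd 0.5) plus 1/f "pink" noise (sd 0.5) per channel, one
independent pink realization per channel per trial — with unit-amplitude
kernels this gives a single-trial peak SNR near 1 per channel, i.e. a
clearly visible evoked response after averaging tens of trials, which is
what combined planar gradients over early visual cortex look like. Gaze
traces use minimum-jerk saccade profiles with main-sequence durations
(≈ 2.2 ms/° + 21 ms), 0.01° RMS tracker noise (a video eye-tracker's
nominal resolution), and Poisson microsaccades (0.25 s⁻¹, ≤ 0.3°,
out-and-back). Latencies are truncated log-normal (median ≈ 230 ms,
log-sd 0.30, support [0.15, 0.5] by rejection), with a per-participant
log-normal jitter (sd 0.08) of the median. A `snap_to_grid` option rounds
cue and saccade times to the sample grid; it exists for the
exact-arithmetic null configurations used in the tests and is off by
default. The event table doubles as the record of the experiment's online
saccade detection, which is why the simulation studies may lock epochs to
it directly.

What the generator does **not** emulate: volume conduction and field
spread (components are independent across sites up to their weight maps),
eye-movement artifacts in the MEG channels, environmental interference
(hence no Maxwell filtering), head movement, and trial-to-trial amplitude
variability of the evoked components. Passing tests therefore validate the
pipeline's arithmetic and its statistical calibration under the stated
model, not robustness to these real-data complications.

## Numerical conventions

0-based sample indices; epoch windows include the sample at both edges
except the baseline window, which is half-open ([−0.6, −0.5)); the
saccade-onset sample is the t = 0 sample of relocked epochs; photodiode
trinary boundaries are four equally spaced values including the min and max
(the four-interior-values reading is flag-selectable); the surrogate
sampler derives one substream per (participant, trial) from the master
seed by key splitting, so results do not depend on execution order; KDE
bandwidth is Silverman's rule on the per-cell latencies, floored at 5 ms;
rank-deficient GLMs fall back to the minimum-norm solution with a warning;
a zero-variance response yields R² = NaN with a warning; cluster p-value
ties are resolved conservatively (null ≥ observed counts as extreme).

## Problem sizes in the tests

The simulation studies run at a desk scale chosen to keep the full suite in
the tens of minutes: 60/30/30 trials, 500 Hz, 8–16 sites, shortened trials,
50–200 surrogate draws, 200 permutations, 8–20 participants per cohort, 50
cohorts for effect recovery and 200 for type-I calibration. The `scale:
"paper-like"` preset restores the full design (416/208/208 trials, 1000 Hz
acquisition, 102 sites, 28 participants, 1000 draws/permutations).

## Known limitations

- **Rectification bias.** Combined planar gradients are non-negative, so
  sensor noise adds a Rice-distribution floor that compresses
  low-amplitude stretches of the evoked traces. Because the templates are
  averaged over fewer trials than the combined condition, they are
  compressed more, which inflates β̂_stimulus by some tens of percent at
  30-trial templates (the effect shrinks roughly as 1/n_trials and is a
  few percent at the 208-trial full design). The zero-noise configuration
  recovers β_true to 1e-6, pinning the arithmetic; the bias is a property
  of rectified evoked statistics, not of the solver.
- **Surrogate regressor sampling noise.** Each surrogate iteration
  regresses Y on a single random scramble realization of the Stimulus-only
  template. That realization's latency-sampling noise acts as measurement
  error in the regressor; the resulting attenuation leaves a small,
  systematic, stimulus-shaped positive component in the median residuals
  that is shared across participants. At desk-scale trial counts this is
  large enough to make the *end-to-end* null (no injected residual, full
  generator) reject far above the nominal rate, so end-to-end null cohorts
  must not be used to calibrate the cluster test. The cluster-permutation
  machinery itself is exactly calibrated for exchangeable null maps (the
  type-I study in the tests), and the pure-noise and zero-noise
  configurations — where the GLM's error-free-regressor assumption holds —
  are well behaved. A pooled variant that averages all draws into one
  expected-scramble regressor (reducing the sampling noise by a factor
  n_draws) is available via `surrogate_regressors` + a single GLM fit, but
  the per-iteration median is the default because it is the procedure the
  analysis defines.
- The duration criterion, adjacency radius, cluster-forming threshold and
  permutation count are conventions, configurable but defaulted as stated
  above; results near threshold can depend on them.
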