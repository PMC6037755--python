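# Methods

This note documents the models, estimators and design choices behind
`attnvar`: what the synthetic-experiment generator does and does not
emulate, how each analysis stage is defined, and the numerical conventions
that matter when reproducing results.

## Task and stimulus model (`attnvar.stimulus`)

Two dynamic Gabor streams change orientation every 10 ms frame over a grid
of 36 orientations spaced 5° apart on [0°, 175°]. The zero-coherence
period (ZCP) stream concatenates independent uniform permutations of the
36 orientations, so every orientation appears exactly once per 36-frame
block; a consequence (asserted by exhaustive scan in the tests) is that no
orientation can appear more than twice in any 30-frame (300 ms) window.
Sequences are generated from five per-session seeds and are
prefix-stable: the first k frames are identical regardless of the trial's
duration, which is what makes same-seed trials "identical repetitions"
for correlation analysis.

ZCP durations follow an exponential distribution bounded to
[0.01 s, 5 s]. The printed mean of 2.17 s is interpreted as the mean of
the *bounded* distribution (it describes what subjects experienced), so
the underlying rate is calibrated by root-finding on the closed-form
truncated-exponential mean; the naive rate 1/2.17 would give a bounded
mean of only ~1.6 s. Draws use inverse-CDF sampling of the conditioned
distribution; the tests check the empirical CDF against the analytic one
(Kolmogorov distance < 0.01 at n = 10⁵) and the calibration against
numerical quadrature of the truncated density.

The 300 ms coherent period (CP) places exactly `coherence` signal frames
(135° left / 45° right) uniformly at random among its 30 frames — not
necessarily contiguous — and background CP frames are resampled away from
the signal orientation so the designed signal count equals the coherence
exactly. Whether chance background occurrences should count toward the
coherence is ambiguous in the source description; we count designed frames
only, and the permutation-block cap (≤ 2 chance occurrences per 300 ms)
bounds the discrepancy. A further 200 ms of ZCP follows the CP for the
behavioral response.

Schedules cue attention in blocks that terminate after 60 hit-or-miss
trials (false alarms and catch trials do not count), randomized in sets of
three so each condition appears before any repeats. Catch trials are
independent Bernoulli(0.10) per trial rather than exact quotas. AB
coherences are the base set plus one frame (difficulty balancing); the
shifted set is used as-is without re-deduplication. When a schedule is
materialized without outcomes (`build_session_schedule`), non-catch trials
stand in for hits/misses; the outcome-coupled rule is exposed through
`TrialScheduler.record_outcome` and used by the simulation loop.

## Generative population model (`attnvar.simulate`)

Each unit fires as an inhomogeneous Poisson process at 1 ms resolution
(Bernoulli thinning per bin; exact at these rates), with

    λ_i(t) = drift_b · [ offset_i(s) + gain_i(s)·A_i·VM(θ(t − ℓ_i)) + b_i
                         + c_i·z(t) ]₊

where VM is a von Mises bump on the doubled orientation angle
(κ ≈ 1.5, so ~0→1 modulation across orientations), ℓ_i = 50 ms latency,
b_i ≈ 8 spikes/s baseline, A_i ≈ 38 spikes/s amplitude (grand mean rate
≈ 22 spikes/s), z(t) a shared Ornstein–Uhlenbeck noise (SD 3 spikes/s,
τ = 30 ms) producing fast-timescale correlations identical across
conditions, and drift_b a per-block log-normal random walk (SD 0.04)
exercising the block-wise normalization non-trivially.

The latent attention state s(t) selects which stimulus receives the
attentional gain. AI/AO hold the state fixed; a shared log-normal jitter
(SD 0.03) perturbs attentional strength trial-to-trial in all conditions.
In AB the initial target is Bernoulli(½) and, with probability
`p_hold` = 0.5, held for the whole trial; otherwise it switches as a
telegraph process with mean dwell 250 ms (4 Hz). The hold/switch mixture
is deliberate: a pure memoryless 4 Hz telegraph decorrelates within
~125 ms and would place most of the AB correlogram separation *before*
200 ms, whereas trial-to-trial target commitment adds the trial-constant
component that makes r_CCG(AB) diverge from AI/AO only at long
timescales — the defining signature of attentional fluctuation at the
trial scale.

Attention couples to units as pure gain (32% of units), pure offset
(20%) or both at half strength (the remainder), matching the reported
population split. The gain separation between attended and unattended
states scales with the horizontal eccentricity of the stimuli,
sep = 0.01 + 0.29·(ecc − 3°)/6°: nearby stimuli can be covered jointly
(near-zero separation, hence little AB-specific variance), distant ones
force genuine switching. Offset-coupled units use an additive step of
20·sep spikes/s so all coupling classes share one separation scale. This
mapping is the package's design choice — the source reports only that the
correlation contrast grows with eccentricity — and it is sized so that
the 30-session batch has adequate power for the across-session trend
test.

A known tension: with attention acting as a common gain, the AI-vs-AO
mean-rate difference and the AB correlation contrast are coupled (the
contrast scales as separation², the rate difference as separation). At
the reduced simulation scale used throughout (10 units, 600 trials per
session, 30 sessions — chosen so a full batch runs in minutes), a
separation small enough to produce a ~5% rate difference would make the
correlation contrast statistically undetectable. The defaults therefore
favor the correlation structure; the resulting AI-vs-AO rate elevation is
~12%, larger than in the motivating data. Conclusions about rate
modulation magnitudes should not be read off this generator.

Behavior: detection is logistic in coherence with location 3.2 frames
when the changed stimulus is the attentional target at CP onset and 5.5
when it is not (slope 0.8, 2% lapse). In AI/AO the cue is 100% valid, so
the changed stimulus is always the target; in AB it depends on the latent
state — this alone reproduces the elevated AB threshold (~4.4 vs ~3.3).
False alarms arise from a constant 0.25 s⁻¹ hazard during the ZCP
(~35–40% FA rates); reaction times are gamma-distributed inside the
[CP + 100 ms, CP + 500 ms] response window. Eye traces are 1 kHz OU
fixational jitter (SD 0.01°) with planted microsaccades (0.2–1°,
10–30 ms, ≥ 50 ms apart) and a ground-truth sidecar; the laminar LFP is a
Gaussian-profile dipolar sink at a configurable channel with smooth
noise, built so the discrete second spatial derivative recovers the sink
channel exactly in the noiseless limit.

What the generator does **not** emulate: spike-waveform realism and
sorting errors, non-Poisson spiking (refractoriness, bursting), saccade
main-sequence kinematics, biophysical LFP structure, reward and learning
dynamics, and the layer-dependence of attentional effects (unit depths
are assigned but all units share one attention model). Passing tests
therefore certify the *estimators* — recovery of planted parameters,
calibration of null distributions, exact statistical identities — not the
biological fidelity of every data feature.

## Analyses

**Spike detection** (`spikedetect`): events where the trace crosses
5·σ with σ = median(|x|)/0.6745 (the Gaussian MAD constant, robust to
spike contamination); negative-going polarity by default (extracellular
convention; configurable), per-channel σ; alignment to the center of mass
of the rectified segment above half peak. Scale equivariance and the
Gaussian false-positive tail are tested.

**Tuning** (`tuning`): 10 ms spike counts regressed on a one-hot encoding
of the 15 frames preceding each bin (lags 1–15; lag 0 excluded), with an
intercept (min-norm least squares; the one-hot blocks are collinear with
the intercept, but the across-orientation weight *pattern* is
unaffected). Optimal latency = lag with the largest across-orientation
weight variance, ties to the smaller lag; the curve is re-estimated at
that single lag (group means in a centered parameterization). Tuning fits
use the full ZCP rather than the first second: with only five distinct
seed sequences, identifiability of the 541-parameter design needs the
long trials. Tuning significance projects the weight vector onto a
one-cycle complex exponential; the permutation null shuffles responses
against stimuli and **re-runs the entire procedure** — joint-fit lag
selection then single-lag refit — per shuffle (the joint normal matrix is
stimulus-only, so its pseudoinverse is computed once and each shuffle
costs one mat-vec). Testing at a fixed pre-selected lag is
anti-conservative (type-I ≈ 0.075 at α = 0.05); the full replication is
calibrated (the acceptance suite checks type-I ∈ [0.03, 0.07] over 500
null units). p-values use (1 + #{null ≥ obs})/(1 + n_perm).

**Spike density functions**: 50 ms bins, averaged over trials within
(condition, seed), then over seeds; Gaussian-smoothed with SD = 1 bin
(kernel width is a package choice); session SDFs normalize unit SDFs by
the AO-condition mean from 100 ms post-onset onward.

**Von Mises condition fits** (`vonmises`): four-parameter fit on the
doubled angle (the 180°-periodic tuning maps onto one von Mises period;
the doubling convention is isolated in one transform), multi-start over 8
preferred-orientation initializations, `scipy.optimize.least_squares`
with tolerance 1e-8, w3 bounded to [0, 20] (beyond which the basis
overflows and the curve is a grid delta). Condition regression on
per-orientation mean responses, weighted by trial counts when provided;
omnibus F (full vs β0+β1 reduced model) at α = 0.05 gates
classification; then two-sided t-tests on β2 (offset) and β3 (gain), no
further correction. F and t statistics are validated against the
F = t² identity for single-parameter restrictions.

**Correlations** (`correlations`): counts in 0–200 ms and 0–1000 ms
windows post-onset, ZCP only, correct trials only, trials shorter than
the window excluded. Z-scoring cell = (unit, seed, attention block);
cells need ≥ 3 trials and nonzero SD, sparse cells fall back to (unit,
seed) pooled statistics — the cell definition and fallback are package
choices. Unbiased (n−1) variances throughout. Fano factors use the same
cells, combined across cells by trial-count weighting. The session
contrast is r_AB − (r_AI + r_AO)/2, defined only when all three condition
means exist.

**Correlogram timescale** (`timescale`): 1 ms binned trains over the
first 1000 ms; raw correlograms and seed-matched shift predictors (from
per-seed trial-averaged PSTHs) are accumulated in the frequency domain
(one FFT per unit per trial, cross-spectra for all pairs at once).
Corrected correlograms keep per-trial-average coincidence *sums*; the
triangular (T − |τ|) normalization is applied only for display, since it
would apply to raw and predictor alike and cancels in the correction.
The zero-lag auto-correlogram bin retains the spike-count term, which is
exactly what makes r_CCG(T) equal the Pearson correlation of T-window
counts (verified to ~1e-9 in the tests; the acceptance suite checks
|r_CCG(1000) − r_sc| < 0.01 on 2000 stationary trials). Session r_CCG
curves average pairs within a session, then sessions.

**Behavior** (`behavior`): hits require a saccade to the changed stimulus
within [CP + 100 ms, CP + 500 ms]; earlier saccades, and saccades to the
unchanged stimulus, are false alarms (the wrong-target case is a package
convention). Psychometric fits are Bernoulli maximum-likelihood logistic
regressions (statsmodels GLM) of hit/miss vs coherence, threshold_50 at
the fitted location, with bootstrap percentile CIs (2000 trial resamples
by default); complete separation is flagged degenerate rather than fit.
Reaction-time distributions are summarized by both the median and the
median absolute deviation.

**Microsaccades** (`microsaccades`): 10 ms displacement > 0.1° (10°/s),
adjacent supra-threshold samples merged, events spanning NaN gaps
rejected; direction bins are eight 45° sectors centered on the cardinal
and oblique axes (bin 0 = [−22.5°, 22.5°)). Rates are per analyzed ZCP
second, normalized by the session mean; direction distributions are
per-bin proportions of session totals (the normalization is a package
choice). The detector achieves ≥ 95% recall and precision on planted
events and is translation-invariant.

**CSD and layers** (`csd`): CSD_j = −(V_{j−1} − 2V_j + V_{j+1})/h²
(sinks negative, physics sign convention), edge replication at the
boundary channels, Gaussian smoothing over depth and time. The earliest
sink is the channel of the first post-onset excursion reaching half the
global sink extremum. Depth zero-point = first layer-5 channel; granular
= [−400 µm, 0), supragranular below −400 µm, infragranular ≥ 0 (the
−400 µm edge is included in G). Boundary identification is
semi-automatic — the earliest-sink heuristic is a default for an
operator-supplied channel — and a robustness mode re-labels with the S–G
boundary shifted over ±180 µm and reports label stability.

**Session statistics** (`rmstats`): sessions, never units or pairs, are
the units of analysis. One-way repeated-measures ANOVA is computed
directly (and cross-checked against statsmodels' AnovaRM); no sphericity
correction is applied. Tukey–Kramer post-hoc p-values use the
studentized-range distribution with the within-subject error term. The AB
contrast test is a one-sample, one-tailed t on per-session
c = AB − (AI + AO)/2 — one-tailed because the attentional-fluctuation
model predicts the direction a priori. A Bonferroni α helper is exposed
for multiple rate comparisons. Two-factor designs (condition ×
microsaccade direction) delegate to AnovaRM.

**Inclusion** (`pipeline`): a session enters population analyses iff ≥ 10
units are visually responsive (paired t, pre vs post 300 ms) *and*
significantly orientation-tuned in every condition, and ≥ 3 of the 5
seeds have ≥ 3 correct, sufficiently long trials in every condition. All
analyses share one trial-selection rule (correct trials, ZCP only,
window-length requirement) implemented in a single function.

## Reproducibility and problem sizes

Every random stage draws from `numpy` generators spawned from a single
session seed (`SeedSequence`), so identical configurations reproduce
bit-identical sessions. The default batch — 30 sessions × 10 units × 600
trials, eccentricities spread over 3–9° — was sized to run the full
simulate-plus-analyze cycle in a few minutes while leaving the
session-level tests (ANOVA, one-tailed contrast, eccentricity trend)
properly powered; per-session estimates at this scale are individually
noisy, and all directional claims are made at the batch level.

## Known limitations

- The generator's rate-vs-correlation coupling (above) overstates the
  AI-vs-AO rate difference when the correlation structure is calibrated.
- The AB hold/switch mixture is a two-timescale caricature of attentional
  dynamics; quasi-periodic (theta-band) attention sampling is not modeled.
- Laminar labels are assigned but attention effects are not
  layer-dependent in the generator, so laminar contrasts carry no signal
  here.
- The STA receptive-field mapper assumes the dot log's epoch clock and
  the spike clock are already aligned.
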