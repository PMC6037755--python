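# attnvar

Analysis pipeline and synthetic-experiment generator for studying how
fluctuations in attentional state shape shared variability ("noise
correlations") in primary visual cortex population recordings.

## The scientific problem

When a subject performs a covert spatial attention task, the experimenter
controls the cue but not the subject's moment-to-moment attentional state.
If the attentional gain acting on a neuronal population fluctuates — from
trial to trial or within trials — all gain-modulated neurons covary
together, and this internally generated signal masquerades as "noise"
correlation. The paradigm modeled here dissociates attentional *strength*
from attentional *variability* with a cued orientation change-detection
task and three conditions: Attend-In (AI, the change always occurs in the
stimulus over the recorded neurons' receptive fields), Attend-Out (AO, the
change is always in the opposite hemifield) and Attend-Both (AB, 50/50).
In AI/AO the optimal strategy pins attention to one location; in AB it
forces attention to cover — or switch between — both, maximizing
attentional-state variability.

The key statistics:

- **r_sc** — the Pearson correlation of two units' spike counts over
  repeated presentations of *identical* stimulus sequences (the dynamic
  orientation noise is seeded, so five frozen sequences repeat across
  conditions), z-scored block-wise to remove slow excitability drift.
- **r_CCG(τ)** — the timescale-resolved correlation: with C_jk(τ) the
  shift-corrected cross-correlogram (raw correlogram minus the
  cross-correlation of the two units' seed-matched spike density
  functions), A_jk(τ) = Σ_{|t|≤τ} C_jk(t) and

      r_CCG(τ) = A_jk(τ) / sqrt(A_jj(T) · A_kk(T)),  T = 1000 ms.

  At τ = T this equals the spike-count correlation of T-ms counts exactly
  (the zero-lag auto-correlogram bin keeps the count term), which the test
  suite verifies to machine precision.
- **Von Mises condition fits** — tuning Y = w1 + exp(w2 + w3·cos(x − w4))
  on the doubled orientation angle; shape (w3) and preference (w4) fixed
  across conditions, and a linear regression
  y = β0 + β1·θ + β2·X + β3·θ·X (θ the tuning basis, X the condition
  indicator) classifies attentional modulation as gain (β3), offset (β2) or
  mixed via an omnibus F-test and coefficient t-tests.

Because no public dataset exists for this paradigm, the package includes a
first-class synthetic-experiment generator (`attnvar.simulate` /
`attnvar.pipeline`) implementing the attentional-fluctuation model: a
latent per-trial attention state that is constant in AI/AO and, in AB,
either held for a trial or switching between the two stimuli at ~4 Hz.
Every analysis stage is validated against this generator's ground truth.

## Worked example

Simulate and analyze one session (10 units, 600 trials, ~12 s):

```python
from attnvar.pipeline import SessionConfig, simulate_session, run_session_analysis

cfg = SessionConfig(session_seed=7)
data = simulate_session(cfg)
res = run_session_analysis(data)

print(f"included: {res.included}")
print(f"grand mean rate: {res.mean_rate_hz:.1f} spikes/s")
for cond in ("AI", "AB", "AO"):
    thr = res.thresholds[cond].threshold_50
    row = res.rsc[(res.rsc.condition == cond) & (res.rsc.window_ms == 1000)]
    print(f"{cond}: threshold {thr:.2f} frames, "
          f"r_sc(1000 ms) {float(row.r_sc.iloc[0]):+.3f} "
          f"({int(row.n_trials.iloc[0])} trials)")
print(f"AB correlation contrast: {res.contrast_1000:+.3f}")
```

prints

```
included: True
grand mean rate: 21.6 spikes/s
AI: threshold 3.41 frames, r_sc(1000 ms) +0.021 (49 trials)
AB: threshold 4.33 frames, r_sc(1000 ms) +0.023 (36 trials)
AO: threshold 3.62 frames, r_sc(1000 ms) -0.007 (43 trials)
AB correlation contrast: +0.015
```

Reading the output: the session passes the inclusion rule (≥ 10 visually
responsive, orientation-tuned units in every condition; ≥ 3 valid stimulus
seeds); firing rates sit near the ~22 spikes/s the dynamic stimulus drives;
the psychometric 50% threshold is elevated in AB (the subject needs ~1
extra signal frame when attention must cover both stimuli); and the
spike-count correlation at the 1-second window is highest in AB. Any
single session is noisy — the population-level statistics (repeated-
measures ANOVA across sessions, one-tailed AB-contrast t-test, and the
correlation-contrast-vs-eccentricity trend) are computed by
`attnvar.pipeline.run_batch` / `batch_statistics`:

```python
from attnvar.pipeline import run_batch, batch_statistics
stats = batch_statistics(run_batch(n_sessions=30, base_seed=0))
```

On this default 30-session batch the AB threshold exceeds AI/AO, mean
r_sc(AB) exceeds r_sc(AI) ≈ r_sc(AO) (one-tailed contrast p < 0.001), the
r_CCG(AB) curve separates from AI/AO only beyond ~200 ms, and the AB
correlation elevation grows with stimulus eccentricity.

A thin CLI wraps the same functions:

```sh
attnvar simulate --seed 7 --out bundle/     # session bundle (CSV + HDF5)
attnvar analyze  --seed 7 --out results/    # result tables + summary.json
attnvar report   --results results/
```

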