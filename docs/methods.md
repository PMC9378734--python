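# Methods

This document records the generative model, the default parameters, what the
generator is and is not meant to capture, the numerical conventions, and the
known limitations of the analyses.

## Generative model

### Task

Each trial presents a cue at one of four landmark positions arranged on a
square (eccentricity ≈ 14°, diagonal ≈ 28°), followed after a variable delay
by a target at the cued location (cue validity is 100%). Spike counts are
Poisson in 10 ms bins over three 300 ms segments: pre-cue, pre-target
(cue-to-target delay), and post-target. Trials end in one of three outcomes:
`hit`, `miss`, or `fa` (false alarm).

### Latent states

Two scalar AR(1) states evolve across trials (coefficient 0.7, innovation SD
scaled for unit stationary variance):

* **s1 — shared gain / "optimality"**: s1 enters the rates through the even
  transform `o = E|s1| − |s1|` (zero-mean, maximal when s1 is near zero).
  Firing is multiplied by `1 + w_s1·o`, so trials with extreme s1 (either
  tail) have reduced shared gain. Because o is a *shared multiplicative*
  factor, trial-to-trial variance in o produces positive pairwise noise
  correlations; the wider the within-condition spread of o, the larger they
  are.
* **s2 — linear excitability**: added to the baseline rate as `w_s2·s2`. It
  shifts mean rates linearly and orders the outcomes monotonically.

### Attention

The attentional spotlight on each trial is the cued location plus isotropic
Gaussian jitter (SD 8°). The **target-to-attention distance (TA)** is the
Euclidean distance between spotlight and target, binned as close (0–6°],
medium (6–12°], far (12–18°). Units have spatial response fields; attention
multiplies their rate by `1 + g·K(distance from spotlight to RF center)`
where K is a monotone-decreasing logistic kernel (midpoint 9°, width 2.5°)
with a plateau near the RF — the plateau prevents spotlight jitter from
injecting shared rate variance when attention sits squarely on or far from
the RF. Attention gain applies only after cue onset (pre-target and
post-target segments), which the selectivity analysis exploits.

### Outcome link

Outcomes follow a three-way multinomial logit:

```
eta_hit  = 5.6 − beta_ta·TA + 0.6·s2
eta_miss = 1.1 + 2.0·max(s1, 0) + 1.4·s2
eta_fa   = −3.4 + 16·max(−s1, 0) − 1.4·s2
```

TA degrades hits; the two tails of s1 drive misses (distractibility) and
false alarms (impulsivity); s2 orders the outcomes linearly (miss > hit >
fa in mean s2). The asymmetric s1 slopes (soft miss, sharp fa) make both
error types sit at equally low mean optimality while misses span the wider
optimality range — this plants the noise-correlation ordering
**hit < fa < miss** (hits have the least shared-gain variance, misses the
most) without giving the two error types different mean optimality.

### Population

48 units by default, with planted roles: 20% attention-only (spatial tuning,
no state loadings), 20% outcome-only (state loadings, no spatial tuning),
45% mixed, 15% none. Baseline rates average 30 Hz; tuning gains 2.5–4.0.
RF centers coincide with the landmarks (`rf_scatter=0`), giving the TA signal
a clean low-rank geometry that a 48-unit session can support. State loadings
scale as `w_s1_scale=0.75` (fractional gain) and `w_s2_scale=9.0` Hz.

The `overlap_mix` parameter rotates each unit's s1 loading into its spatial
tuning direction: at high mix the outcome (gain) axis and the attention axis
share the same neural subspace. `simulate_sessions` sweeps `overlap_mix` over
[0.02, 0.98] anti-parallel to `beta_ta` over [0.30, 0.10] across sessions,
planting the across-session negative correlation between axis overlap and
attentional behavioral gain: sessions whose state axis intrudes on the
attention subspace are the sessions where behavior depends least on spotlight
position.

### Scope of the generator

The generator is a *mechanism-level* simulator for validating the analysis
chain, not a biophysical model: Poisson counts with piecewise-constant rates,
stationary AR(1) states, a single spotlight per trial, no adaptation, no
oculomotor dynamics, and a minimal evoked transient on responded trials. It
plants exactly the structures the analyses claim to detect (TA-dependent
behavior, state-linked noise correlations, separable vs. overlapping
subspaces, cross-trial persistence) so that recovery can be scored against
ground truth.

## Analysis conventions and numerical choices

* **Decoder** (`fit_regole`): ridge regression on centered responses with an
  intercept refit; λ = 0 on a collinear design raises `LinAlgError`
  explicitly (condition number > 1e12). `lam="auto"` selects λ from a log
  grid by generalized cross-validation via SVD. The rolling decoder trains on
  the last 200 correct trials and retrains every 20 correct responses;
  decoding windows are −220 to +30 ms (training) and −150 to 0 ms (testing)
  around target onset.
* **Selectivity**: MI = (FR1 − FR2)/(FR1 + FR2) on median rates in the
  −250 to −50 ms pre-target window. The attention test statistic is the
  pre-target response normalized by the same trial's pre-cue response
  (ratio of +0.5-smoothed counts): attention is deployed only after the cue,
  so the ratio cancels slow trial-wise excitability common to both epochs
  that would otherwise swamp the attention contrast on state-modulated
  units. The outcome test uses the pre-cue rate, which carries the
  state modulation free of the attention confound. Both tests are two-sided
  Mann-Whitney at α = 0.05.
* **Noise correlations**: 200 ms pre-stimulus windows, per-channel z-scoring
  with sample SD (ddof = 1), per-cue condition means removed, and summary
  statistics over positive significant pairs only (source convention). TA
  equalization subsamples trial types to matched TA-bin compositions over 20
  seeded resamples.
* **dPCA** (from scratch): exact factorial marginalization (the pieces sum to
  the centered tensor to machine precision; time-interaction terms fold into
  their parameter's marginalization), then a reduced-rank ridge regression
  per marginalization (`W = X_φ Xᵀ (X Xᵀ + λ‖X‖² I)⁻¹`, SVD truncation).
  Condition tensors built from single trials are balanced by seeded
  subsampling to the minimum cell count, averaged over 10 resamples. λ is
  selected by held-out-trial cross-validation over a log grid. Axis decoding
  uses hold-one-trial-per-class nearest-class-mean classification with an
  exact permutation p-value `p = (1 + #{shuffle ≥ observed}) / (n_shuffles + 1)`
  and the max-shuffle accuracy as the chance threshold. Component signs
  follow a fixed convention (largest-|element| of each decoder positive) so
  fits are bit-reproducible. SVD falls back to the `gesvd` LAPACK driver on
  the rare `gesdd` non-convergence.
* **Session overlap**: the overlap statistic between the attention and
  outcome axes is the mean over 3 seeded repeats of |d_ta · d_outcome|,
  where each repeat draws a balanced TA × outcome tensor, collapses it to
  single-parameter tensors, and fits each parameter's first dPCA axis at a
  cross-validated λ. Collapsing from the *balanced* joint tensor keeps each
  axis estimate composition-controlled.
* **Determinism**: every stochastic step takes an explicit seed; session
  seeds derive from the master seed via `numpy.random.SeedSequence`
  spawning. Two `run_all` invocations with the same config produce
  byte-identical reports.

## Limitations

* **Overlap-vs-gain power**: with 18 sessions the planted negative
  correlation is reliably negative in sign at every master seed tested, but
  its p-value clears 0.05 in roughly two-thirds of master seeds; the
  acceptance battery uses a seed where it does. More sessions (or wider
  planted sweeps) would raise power; the per-session overlap estimate is the
  noisiest ingredient.
* **Demixing cost under decoded TA bins**: with decoder-estimated bins the
  single-vs-joint decoding difference is near zero and unstable — decoding
  error smears trials across bins, leaving residual confound signal even in
  the balanced joint tensor. The demixing-cost *examples* therefore use
  oracle (planted) TA bins, where the overlapping-subspace plant yields a
  consistent positive cost and the orthogonal plant none. On real data the
  statistic should be interpreted as a lower bound.
* **Equalized noise-correlation contrast**: TA equalization shrinks trial
  counts; the planted hit < fa < miss ordering survives equalization in
  aggregate and as "hit lowest" in ≥ 80% of sessions, but the fa/miss
  ranking within a single session is noisy. Session-level claims should use
  the hit-vs-error contrast; the full three-way ordering is an
  across-session (aggregate) statement.
* **U-shaped component recovery**: the gain component's projections are
  compared to the planted optimality `o = E|s1| − |s1|`, not to s1 itself —
  an even readout of s1 is uncorrelated with s1 by symmetry. The linear
  component's |ρ| with s2 exceeds 0.5 in median across sessions but not in
  every session (the s2 signal shares variance with the evoked and gain
  structure at session size).
* **Rate floor**: rates are floored at zero after applying the state gains; a
  warning is raised if more than 15% of unit-trials hit the floor, which
  indicates implausibly large loadings for the chosen baselines. At the
  defaults the floor engages rarely and the Poisson means stay effectively
  log-linear in the planted states.
* The per-unit selectivity tests and the axis-decoding permutation test hold
  their nominal type-I error (≈ 5%) under full label-permutation nulls; the
  calibration harnesses permute labels, which tests exchangeability but not
  misspecification under temporally structured nulls (e.g. drifting rates
  without states).
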