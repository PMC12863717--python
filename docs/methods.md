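# Methods

This note records the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic
cohorts do and do not emulate, and the numerical decisions taken where
the design was genuinely open.

## The nDKL framework

All rate comparisons treat inter-poke intervals as exponential, i.e.
poking as a Poisson process within a context.  The divergence of one
exponential from another depends only on the rates,
`D(λ_X‖λ_Y) = ln(λ_X/λ_Y) + λ_Y/λ_X − 1`, and the statistic
`nDKL = n_e·D` with effective sample size `n_e = n_X/(1 + n_X/n_Y)` is
Γ(½, 1)-distributed when the true rates are equal.  We compute the tail
through scipy's gamma distribution; the identity
`Γ(½,1).sf(x) = χ²(1).sf(2x)` is asserted in the tests so either special
function may be substituted.  Everything is kept in nats internally
(1 nat = log₂e ≈ 1.44 bits); fractional effective sample sizes are kept
exact.  When a rate is zero or a sample empty, the statistic is returned
as *undefined* rather than a pseudo-count — the single exception is the
terminal ITI rate, where a recorded count of zero becomes 0.5 (an
unbiased stand-in for a true count between 0 and 1) so its log is
defined.

Directionality: a divergence is a magnitude.  We attach a sign (+ when
the CS rate exceeds the contextual rate) for plotting and for the
permanence criterion, but p-values are always computed from the
magnitude.

## Acquisition criteria

The contextual sample pools CS and pre-CS pokes over their combined
exposure, so the CS is part of its own context; before learning the two
cumulative rates estimate the same quantity and their difference hovers
around zero.  The primary criterion is the trial from which the
difference stays strictly positive for the remainder of the record;
reinforcements-to-acquisition is that trial minus one.  Ties (an exact
zero) count as not-greater, and trials where a statistic is undefined
are skipped when judging permanence.  "Permanently" is evaluated within
the observed record only — the analysis is retrospective over a
fixed-length training history, and no extrapolation is attempted.

Statistical thresholds (odds 4:1 → 0.82 nats, 19:1 → 1.92, 99:1, 999:1)
are applied to the nDKL recomputed *from the exceedance trial onward*:
pre-acquisition trials estimate the same rate in both samples and only
dilute the evidence, inflating trials-to-criterion.  A self-consistent
variant that restarts the cumulation at the candidate trial itself is
available (`fixed_point_exceedance`) but is not the default.  The trial
of the minimum signed nDKL is reported as a secondary marker only; it
localises acquisition well when responding first dips below baseline and
poorly otherwise.

## Rate parsing

The parser segments an inter-poke-interval vector greedily: score every
candidate truncation point, truncate at the maximum if it exceeds the
decision criterion `c`, recurse on the remainder.  The score at a split
after `n_s` of `n` intervals is the *two-part coding cost*

    nDKL(n_s) = n_s·D(λ_prefix‖λ_full) + (n − n_s)·D(λ_rest‖λ_full),

the extra cost of encoding both sub-sequences at the pooled rate.  This
is algebraically the exponential generalised-likelihood-ratio statistic
for a single change point, and it is Γ(½, 1) under the null, so `c`
keeps the same odds/p-value reading as every other nDKL in the package
(c = 6 nats is exceeded by chance roughly once in 1800 tests).  We note
that scoring the prefix term alone (one reading of a prefix-versus-full
comparison) has essentially no power: the full-sequence estimate
contains the prefix, and the contrast saturates below practical
criteria.  The two-part form is the completion of that comparison and is
the package's design choice.  Ties at the maximum break toward the
earliest index (conservative about late structure); recursion applies to
the post-truncation remainder only; the default `c` is 6 nats with 2 and
4 supported.

CS interval vectors follow the corrected-rate conventions (below): each
CS's first poke is not a countable event, so a CS with k pokes
contributes k−1 head-out gaps and single-poke or empty CSs contribute
nothing.  Pre-CS vectors use raw counts on the concatenated pre-window
timeline, with the first entry being time-to-first-event.  A
consequence, inherited deliberately: the first segment's rate estimate
extends back to the start of observation, so a long-but-plausible wait
before the first response does not split off as its own segment.  The
parse-based acquisition trial is the smallest t such that the parsed CS
rate exceeds the parsed pre-CS rate on at least 95% of trials after t.

## Corrected response rates and the scalar law

A poke occupies the head; time in the magazine is time during which no
poke can start.  Corrected rates therefore divide adjusted counts by
exposure minus head-in time; CS rates additionally drop each CS's first
poke and its latency (first-poke latencies, floored near 2 s by travel
time and the 2 s minimum CS, come from a different distribution than
inter-poke gaps).  First-poke exclusion applies to CS rates only, never
to pre-CS rates.  Terminal behaviour uses the last 5 sessions by
default, 10 as an option.

Rate-law regressions are in log base 10 throughout (the shift between
the CS and ITI laws is reported in log₁₀ units, e.g. 0.28 ↔ a factor
10^0.28 ≈ 1.9).  The model ladder: one free line; one slope-1 line (the
scalar law proper — through the origin in the linear domain); separate
slope-1 lines per context; and the shifted-shared model, a single slope-1
scaling with the ITI reinforcement rate uniformly rescaled by a fitted
factor (the contextual rate the subject acts on, overshadowed by the
CS).  With slope fixed at 1 the least-squares intercepts are sample
means of y − x, so those fits are closed-form.  Variants are compared by
`BIC = n·ln(RSS/n) + p·ln(n)`, the same formula used for the growth
curves; a perfect fit (RSS = 0) scores −∞, preserving order.  Group-level
correlations and partial correlations (log median trials-to-criterion
against log(C/T), log C, log T) use product-moment and residual-based
formulas.

## Growth deciles and model comparison

The post-acquisition segment runs from t₁ — by default the odds-4:1
criterion trial, configurable — to the peak of a 3-session centred moving
average of corrected session rates (ties to the earliest window).  R₁ is
the corrected rate of the session containing t₁.  For each decile q of
ΔR = Rmax − R₁ the reference record `(R₁ + q·ΔR)·cumT` is laid over the
observed cumulative record (countable pokes over corrected exposure;
empty CSs contribute their full duration as opportunity-to-respond), and
the argmax of the difference marks the decile trial.  Records with
ΔR < 0.1 responses/s are excluded as non-growers.

The four candidate forms for trials-to-decile t_c(d), with free
parameter counts: line m·d + c (2); exponential c·e^{m·d} (2); inverse
cumulative Gaussian s·√2·erf⁻¹[2(m·d + 0.5) − 1] + c (3); log
−ln(1 − d)/k + c (2).  BIC uses n = 9 points.  The line and log forms
are linear in their parameters and solved exactly; the exponential and
inverse-Gaussian forms run deterministic multi-start least squares (a
log-linear start plus a coarse grid), so fitting involves no randomness.
The inverse-Gaussian's erf⁻¹ argument must stay inside (−1, 1); the fit
is bounded to keep m·d + 0.5 ∈ (0, 1) over d ∈ [0.1, 0.9], and a
non-converged form is flagged with infinite BIC rather than silently
clipped — it reports, but cannot win.  A BIC difference of 4.6
corresponds to odds of 10:1 and is the flag for strong evidence.

## Informativeness, the learning-rate law, and the generative model

Informativeness is ι = C/T, the ratio of the CS reinforcement rate (1/T)
to the contextual rate (1/C); its natural log is the mutual information
CS onset transmits about the wait to reinforcement.  A US-detection
delay δ (a subject slow to find the pellet) stretches both intervals:
effective ι = (C + δ)/(T + δ), a large relative loss precisely when ι is
high.

The learning-rate regression fits log₁₀ median trials-to-acquisition on
log₁₀(ι − 1).  The law is parameterised as `RtoAcq = ((ι − 1)/k)^s` so
that k remains the x-intercept — the excess informativeness producing
one-trial acquisition — even when the fitted slope s differs from −1
(under the alternative k·(ι−1)^s form the intercept reading only holds
at s = −1).  Medians are floored at one reinforcement before taking
logs: one reinforcement is the analytic lower limit of the estimate.

The generative model gives each reinforced trial an independent
probability `p = 1 − e^{−k(ι−1)}` (default k = 1/297) of starting
conditioned responding — a geometric onset time, so the cumulative
probability after n trials is 1 − (1−p)^n and the median onset is the
smallest n reaching 0.5.  The geometric (independent-trials) reading is
the one that produces the cumulative acquisition curves the model is
used for.  Rate estimation theory ascribes observed reinforcement rates
to context and CS by solving [[1, 1/ι], [1, 1]]·ascribed = observed;
the matrix is singular at ι = 1 (the truly random control — credit
cannot be assigned), and negative ascribed rates are reported raw since
no truncation rule is part of the model.

## The synthetic cohorts

The simulator generates what the analysis assumes, with ground truth
exported for scoring:

* **Protocols.**  The 14 standard groups (ι = 1.5–300, Table of
  constants in `events.STANDARD_GROUPS`): CS durations uniform on
  [2, 2T − 2] s; ITIs uniform with minimum 15 s and mean C − T, the
  upper bound mean-centred at 2(C − T) − 15 (this reconstruction matches
  the bracketed ITI ranges of all 14 groups); reinforcement at CS
  offset; 42 daily sessions of 10 trials (3 for the three
  highest-ι groups); a 10 s pre-CS observation window (30 s expressible
  via `ProtocolSpec.pre_cs_window`).
* **Poking.**  A renewal process: exponential head-out gaps at the
  current true rate; poke durations 0.05 s plus an exponential keeping
  the mean at 0.5 s; a 2 s floor on the first poke after CS onset.
* **Acquisition.**  The onset trial is drawn from the generative model
  (k = 1/297).  Before onset, CS and ITI share the contextual rate
  β/(g·C); at onset the CS rate steps to halfway between baseline and
  its terminal value and then ramps linearly to the terminal rate β/T
  over 100 trials (β = 22 the response scalar, g = 1.9 the ITI
  overshadowing factor).  The half-way first step reflects the observed
  structure of response records — the first increment is large, and at
  high informativeness the terminal rate is approached in one or two
  steps — and makes onset detectable on the trial it occurs, which the
  trials-to-acquisition analysis presumes.  Subject-level terminal rates
  carry independent log-normal noise with multiplicative spread 2.5
  (σ_log₁₀ = log₁₀ 2.5 ≈ 0.4) on the CS and ITI scales.
* **Not emulated.**  Session-to-session drift, the post-peak decline
  some low-ι subjects show, US-detection delays early in training,
  within-subject rate steps beyond the single acquisition ramp, and any
  CS-directed competing behaviour.  Passing recovery tests therefore
  shows the estimators are correct for data satisfying the model's
  assumptions, not that real records satisfy them.

Determinism: a cohort is a function of its master seed (per-subject
child seeds are spawned from it); the pipeline's artifacts are
byte-identical across reruns of the same configuration.

## Problem sizes and test design

The recovery studies run at the study's own scale — 14 groups × 12
subjects, 420 or 126 trials per subject — once per property.  The
learning-rate law check regresses group medians over ι ∈ [4, 300]
(the scalar regime; at lower ι a large fraction of subjects do not
acquire within the training given) and judges the slope against −1 with
a subject-level bootstrap confidence interval, since group medians of
12 heavily discretised onset trials are themselves noisy.  The scalar
rate-law check uses a cohort whose subjects acquire early, so that every
subject's terminal window reflects its terminal rate: that isolates the
rate estimators from acquisition timing, which the learning-rate check
covers separately.  Null calibration uses 10⁴ simulated equal-rate pairs
at n = 100 events per sample; parser recovery uses the planted
two-regime configuration (rate ratio 10, 30 + 30 intervals, c = 6) over
200 seeded replicates.

## Known limitations

* The exceedance criterion is noisy on slowly-acquiring subjects: long
  by-chance positive runs of the cumulative difference can precede the
  true onset, and the estimate can lead or lag the generative trial by
  tens of trials at low ι.  This is a property of the criterion, shared
  with the original analysis, not of the implementation.
* The parser is the greedy recursive scheme by contract; it is not an
  optimal multi-change-point segmentation, and an early truncation can
  split a slow drift into several steps.
* Growth-decile extraction assumes an overall monotone rise; records
  with post-peak declines are summarised only up to the moving-average
  peak.
* The Γ(½, 1) null is asymptotic in the per-sample event counts;
  calibration below ~10 events per sample is approximate (the tests
  document the sup-norm CDF distance at the sizes used).
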