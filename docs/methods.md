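# Methods

This note records the statistical model behind `chronosig`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate.

## Data model

An **event stream** is one account's time-ordered posts: integral POSIX
seconds plus a fixed per-account UTC offset in minutes. The timezone model
is deliberately a single constant offset — no DST database — because the
offset is the only timezone information broadcast platforms typically
expose, and the analyses only need hour-of-day resolution. Local clock
features are computed on `t_utc + 60·offset`; weekdays are ISO (Monday=1).

Two derived features drive everything:

* **inter-event delay**: τᵢ = tᵢ₊₁ − tᵢ seconds, floored at 1 s. Flooring
  (rather than dropping) same-second pairs keeps the delay series at
  exactly n−1 entries per n-event stream and gives every delay a positive
  value that the log-binned histograms can absorb. Each delay carries the
  local hour of the *earlier* event ("preceding hour").
* **event hour**: local hour 0–23 of each event.

Streams are capped at the 800 most recent events per account (the typical
crawl depth for this kind of data); accounts without a known offset are
filtered out before any clock-dependent analysis.

## Empirical densities

Delays are histogrammed on 100 logarithmically spaced bins spanning
10⁰–10⁷ s (1 s to ~116 days; configurable). The histogram is normalised to
integrate to one, then empty bins are raised to a **floor** of 10⁻¹²
probability/second (10⁻⁶ per hourly bin for the 24-bin hour mass). The
floor is what makes naive-Bayes log-scores finite when an account produces
a feature value its class never showed in training; because the floor is a
fixed documented constant, scores remain comparable across classes.
Pre-floor values are retained so normalisation stays checkable.

Point evaluation between bin centres uses a monotone shape-preserving
piecewise cubic (PCHIP) in log-delay coordinates, clamped below at the
floor; outside the binned support the floor is returned rather than
extrapolating. PCHIP was chosen over an unconstrained cubic spline because
splines overshoot and go negative on sparse histograms, and a density
evaluator must not.

The joint (delay, hour) density comes in two forms: the **product of the
marginals** (independence assumed) and a **full 100×24 2-D histogram**
(no independence assumption; evaluated by cell lookup). The 2-D variant
deliberately inherits the coarse grid — its weakness on small samples is
subsampling of the joint, and that behaviour is part of what the package
demonstrates.

## Power-law tails

The tail fit follows the standard maximum-likelihood treatment for
continuous data: α̂ = 1 + n[Σ ln(xᵢ/x_min)]⁻¹ over the tail, with x_min
selected by minimising the KS distance between the tail empirical CDF and
the fitted power-law CDF over candidate cutoffs (unique sample values,
log-thinned to ≤200; ties to the smallest cutoff, favouring larger tails).
Delays are second-resolution integers but span seven decades, so the
continuous likelihood is appropriate above any realistic cutoff.

Goodness of fit is a semi-parametric parametric bootstrap: replicates draw
from the empirical head below x_min with probability n_head/n and from the
fitted power law above, are refit from scratch (including cutoff
re-selection), and p is the fraction of replicate KS distances at or above
the observed one.

**Minimum tail size.** A candidate cutoff must keep at least 500 samples
(`min_tail`, a keyword everywhere). This is deliberately conservative: with
small floors (e.g. 50) the KS-minimising cutoff escapes into a short far
tail where *any* smooth distribution — an exponential, say — locally
resembles a power law, and the bootstrap test loses essentially all power.
At 500 the test rejects exponential-tail data (n = 5000) with p ≤ 0.04
across probe seeds while remaining calibrated on true power-law data
(fraction of p < 0.1 about 0.1 over 50 replicates at n = 2000,
n_boot = 100). The bootstrap default of 100 replicates is desk scale; for
publication-grade p-values use 1000.

## Classification

Training pools all events of all training accounts of a class into one
density per class (pooled, not per-account-averaged). The four feature
modes are: delay marginal (`itd`), hour marginal (`tt`, trained on every
event's hour), joint-as-product (`ji`, hour marginal trained on preceding
hours so it matches the paired samples), and the full 2-D joint (`jni`).
An account's class score is the sum of log densities of its feature values
(natural log); classification is argmax of score + log prior. Priors
default to uniform — the evaluation cohorts are balanced — making MAP
coincide with maximum likelihood; ties break deterministically to the
first class in model order (personal, managed, bot, then anything else).

Evaluation schemes:

* **leave-one-out**: retrain on all other accounts for each held-out one;
* **repeated stratified splits**: per class, shuffle and split
  `train_fraction` / rest, ≥1 account on each side, accuracy reported as
  mean ± SD over repeats;
* **chance baseline**: the pooled training *events* are shuffled across
  classes (preserving class event counts), the model retrained, and every
  account scored against its true label. Event-level shuffling is used
  because it makes the pseudo-class densities near-identical mixtures and
  concentrates the baseline tightly around 1/K; account-level label
  permutation leaves whole coherent accounts in each pseudo-class, giving
  the repeat mean a variance far wider than the binomial band (and, if
  combined with leave-one-out retraining, a systematic below-chance bias,
  since holding an account out depletes its pseudo-class of its own data).

The independence premise behind `ji` is checked directly: Pearson r and
Kendall τ between pooled delays and preceding hours per class, which on
both synthetic cohorts and by construction-independent pairs come out
near zero (|r| < 0.05 at n = 10⁴).

## Next-event prediction

The class model is the empirical CDF of pooled training delays (built on
sorted unique values, right-continuous). Each observed delay τ of a test
account defines the step function s(t) = 1{t ≥ τ}, and the model is scored
by R² = 1 − SS_res/SS_tot on an evaluation grid, SS_tot taken about the
mean of the step values (ordinary R²), unclamped — negative values are
informative. Events whose τ falls outside the grid have SS_tot = 0 and are
skipped (counted separately) rather than given an arbitrary score.

**Evaluation grid.** The default grid is a *fixed* set of 200 log-spaced
points spanning the delay-bin decades, shared by every model under
comparison. This is the one place the package departs from the obvious
"use the CDF's own support points" convention, for a quantitative reason:
with quantile-spaced support grids of size G, an extreme τ (at empirical
quantile q near 0 or 1) contributes R² ≈ −1/(3q) ≈ −G/3, so the *mean* R²
scales like −(2/3)ln G — an artefact of grid cardinality, not of model
quality. Hour-conditioned models (≈G/24 points per hour) would then differ
from the single model by ~2 in mean R² on data where the hour carries no
information at all. On the shared fixed grid the two agree to < 0.02, and
model comparisons (class CDF vs the uniform-over-[1, 10⁶] null) measure
distributional fit rather than support size. Any explicit grid can be
passed instead.

The hour-conditioned variant holds 24 CDFs keyed by preceding hour (hours
with fewer than two delays fall back to the unconditional CDF) and selects
per event by the hour of the account's previous post.

Known limitation: the relative *ordering* of per-class mean R² depends on
the grid convention. On the shared log grid, second-scale burst delays sit
at the extreme low end and contribute strongly negative per-event scores,
which dominates the mean and SD for burst-heavy (human-like) classes; a
claim like "bots are less predictable than humans" is therefore not stable
under this convention and is not asserted by the package.

## Activity statistics

* **Periodogram**: plain mean-removed periodogram (boxcar window, one-sided
  density scaling) of fixed-width event counts, frequencies in Hz, power
  optionally in dB/Hz; Σ psd·df equals the series variance.
* **Circular statistics**: hours map to angles 2πh/24; the mean direction
  comes from the resultant vector, κ from the standard piecewise inversion
  of the mean resultant length, and dispersion defaults to 1/√κ (the
  large-κ SD of the equivalent wrapped normal), converted to hours. The
  alternative circular SD √(−2 ln R̄) is available by flag since either
  convention is defensible.
* **Delay scaling**: per-account delay mean and SD with a least-squares
  line and Pearson r; heavy-tailed accounts show SD ≈ mean
  (signal-dependent noise). Proportionality should be read on log-log axes
  (flag): on linear axes the fitted slope is dominated by the few largest
  accounts.
* **Activity matrices**: accounts × weekday/hour counts, rows sorted by
  ascending total, optional top-n. Purely descriptive; weekday/weekend is
  never used in inference.

## Synthetic cohorts

The generator is the package's study population, not a fixture hack. Each
human-like account is a renewal process whose gaps come from a two-part
mixture — with probability `burst_fraction` a log-uniform "burst" gap on
`burst_range`, otherwise a Pareto gap (exponent `tail_alpha`, cutoff
`tail_xmin`) — thinned by a diurnal × weekday acceptance profile: a
candidate event at local time t is accepted with probability
`diurnal_profile[hour] · weekday_weights[weekday]`; a rejected candidate
extends the current gap with a fresh mixture draw. Bots bypass the
mixture: `constant_rate` uses exponential gaps (memoryless, flat hours),
`spike_hours` schedules one event per listed hour per day at half past,
jittered ±10 min. Timezone offsets are drawn per account from a small set
of plausible world offsets; all randomness derives from one master seed
via `default_rng([seed, class_index, account_index])`, so cohorts are
reproducible piecewise.

Default class parameters: personal α = 2.4 (the human broadcast regime),
x_min = 300 s, burst fraction 0.5 on 2–300 s, evening-peaked profile
(argmax 21 h), flat week; managed α = 1.9, x_min = 600 s, burst fraction
0.4 on 5–600 s, work-hours profile with a dip at 12 h and weekends at 0.6;
bot constant rate 1800 s (`bot_variant_specs()` adds faster/slower rates
and spike schedules for heterogeneous bot populations). The cutoffs and
profile amplitudes are package choices.

**Why the diurnal contrast is moderate.** Thinning stretches any gap that
crosses low-acceptance hours, and the stretch factor varies with the hour
— a heterogeneous dilation that deforms the delay distribution in the
decade above x_min. Strong day/night contrast (10×) makes the KS-selected
tail fit mis-estimate the exponent by 0.2–0.4; the alternatives explored
(extending rejected candidates by short re-probes, or exact time-rescaling
through the cumulative intensity) trade the same bias for either a
diluted hour profile or a size-biased stretch with the same net effect.
The shipped profiles (personal trough-to-peak ≈ 1.6×, managed ≈ 3.3×)
keep both guarantees simultaneously: tail-exponent recovery within ±0.15
at 10⁴ events per account, and hour-histogram/profile correlation > 0.7.
The bootstrap GOF accepts the generated tails in the majority of seeds
(the thinning perturbation is real but small).

What the generator does *not* emulate: content or reply structure,
cross-account interaction, non-stationary behaviour (holidays, account
lifecycle), per-account parameter heterogeneity within a class beyond the
timezone offset, and DST. Passing tests therefore demonstrate that the
*methods* behave as claimed on data with the right timing structure — not
that any particular real platform cohort will reach the same accuracies.

## Problem sizes

The reference evaluation cohort is 20 accounts per class × 200 events
(about the event count per account a capped crawl yields); estimator
checks use 10⁵ samples (recovery), 50×100 bootstrap replicates at
n = 2000 (calibration) and 200 replicates at n = 500 (KS type-I rate);
generator recovery uses 10⁴ events per account. These sizes make the whole
suite and the acceptance script each run in well under a minute while
leaving every tolerance dominated by the statistics, not the budget.
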