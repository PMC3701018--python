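# chronosig

Timing signatures of broadcast-communication accounts.

`chronosig` infers **who (or what) is behind an account** — a person, a
managed/corporate presence, or an automated bot — from nothing but the
timestamps of its posts. It is built around three observations about
broadcast posting behaviour:

1. **Heavy-tailed inter-event delays.** The delay τ between consecutive
   posts of one account follows a distribution whose tail decays as a power
   law, P(τ) ∝ τ^(−α) above a lower cutoff x_min, with class-distinct
   exponents (steeper for personal accounts than for managed ones). The
   package fits α by the continuous maximum-likelihood estimator
   α̂ = 1 + n [Σᵢ ln(τᵢ/x_min)]⁻¹, selects x_min by minimising the
   Kolmogorov–Smirnov distance between tail and fit, and attaches a
   semi-parametric bootstrap goodness-of-fit p-value.
2. **Class-distinct daily rhythms.** The local hour-of-day distribution of
   events separates classes: personal accounts ramp up towards an evening
   peak, managed accounts concentrate in work hours with a midday dip, bots
   post at a constant rate or in scheduled spikes.
3. **Both features are nearly independent**, so a naive-Bayes MAP
   classifier over empirical densities works: an account's score for class
   c is Σ_events log p̂_c(feature), with p̂_c the pooled class histogram
   density (log-binned delays × hourly bins), and the account is assigned
   to the argmax class.

A renewal-style predictor closes the loop: the empirical CDF F_c(t) of a
class's pooled delays is read as "probability the next event has occurred
within t seconds", each observed delay τ defines a step function (0 before
τ, 1 after), and the model is scored per event by
R² = 1 − SS_res/SS_tot between CDF and step (unclamped; negative values
mean worse-than-constant prediction).

Because no public dataset with curated account-class labels is durably
available, the package ships a seeded synthetic cohort generator
(`chronosig.synth`) that reproduces these signatures — heavy-tailed gap
mixtures, diurnal/weekly thinning, bot schedules, signal-dependent noise —
and every claim in the test suite is demonstrated against it.

## Worked example

```python
from chronosig import classify, synth, tails
from chronosig.events import compute_delays

# a labelled cohort: 20 accounts per class, 200 events each
cohort = synth.simulate_cohort(synth.default_class_specs(), 20, 200, seed=0).streams

# classify by timing alone, leave-one-out
for mode in ("itd", "tt", "ji", "jni"):
    print(mode, classify.loocv(cohort, mode=mode).accuracy)

# characterise one account's delay tail
delays = compute_delays(cohort[0]).delays
print(tails.fit_power_law(delays))
```

Running `python examples/classify_accounts.py` prints:

```
leave-one-out cross-validation, 60 accounts:
   itd: 100.0 % correct
    tt:  68.3 % correct
    ji: 100.0 % correct
   jni: 100.0 % correct
chance baseline (training data shuffled across classes): 32.8 % +/- 9.6
30 % training split: 100.0 % +/- 0.0
```

i.e. the three classes are fully separable from timing on this synthetic
cohort (the delay marginal alone suffices; the hour marginal alone reaches
68 %), while shuffling the training data across classes collapses accuracy
to the 1/3 chance level. `examples/fit_heavy_tail.py` shows tail
estimation on a personal-class account (α̂ = 2.458 against a generative
α = 2.4, bootstrap GOF p = 0.59), and `examples/predict_next_event.py`
shows the predictor scoring a held-out account at mean R² = +0.63 against
−1.37 for a uniform-random null model. Each script in `examples/` is a
short narrative of one capability.

A thin command line mirrors the library:

```sh
chronosig simulate --n-accounts 20 --n-events 200 --seed 0 --out cohort.jsonl
chronosig evaluate --input cohort.jsonl --scheme loocv --mode ji
chronosig fit-tail --input cohort.jsonl --class personal --n-boot 100 --seed 1
chronosig predict-eval --input cohort.jsonl --class personal --null uniform --seed 1
```

Events are JSON-lines (or CSV) records:
`{"account_id": ..., "label": ..., "t_utc": ISO-8601, "utc_offset_min": int}`.

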