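"""Classify accounts by timing alone and evaluate against chance.

The naive-Bayes classifier scores each account's events against pooled
per-class empirical densities (MAP rule, uniform priors). Four feature
modes: delay marginal (itd), hour-of-day marginal (tt), their joint under
independence (ji) and the full 2-D joint (jni).
"""

from chronosig import classify, synth

cohort = synth.simulate_cohort(synth.default_class_specs(), n_accounts_per_class=20,
                               n_events=200, seed=0).streams

print("leave-one-out cross-validation, 60 accounts:")
for mode in ("itd", "tt", "ji", "jni"):
    report = classify.loocv(cohort, mode=mode)
    print(f"  {mode:>4}: {100 * report.accuracy:5.1f} % correct")

chance = classify.shuffled_baseline(cohort, mode="ji", n_repeats=10, seed=1)
print(f"chance baseline (training data shuffled across classes): "
      f"{100 * chance.mean_accuracy:.1f} % +/- {100 * chance.sd_accuracy:.1f}")

report = classify.split_evaluate(cohort, mode="ji", train_fraction=0.3,
                                 n_repeats=10, seed=2)
print(f"30 % training split: {100 * report.mean_accuracy:.1f} % "
      f"+/- {100 * report.sd_accuracy:.1f}")

# Correct classification far above the ~33 % chance level shows the three
# classes are separable from event timing alone, with no content features.
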