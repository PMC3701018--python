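"""Predict the distribution of an account's next inter-event delay.

The class-level model is the empirical CDF of the class's pooled delays:
F(t) = probability the next event happens within t seconds. Each observed
delay tau defines a 0/1 step function, and the model is scored per event by
R^2 between CDF and step (negative = worse than a constant predictor).
"""

import numpy as np

from chronosig import classify, predict, synth

cohort = synth.simulate_cohort(synth.default_class_specs()[:1], 20, 200, seed=0).streams
feats = [classify.featurize(s) for s in cohort]

held_out, rest = feats[0], feats[1:]
model = predict.build_single_model(
    np.concatenate([f.delays for f in rest]), label="personal")
null = predict.uniform_null_model(seed=5)  # uniform over 1 .. 1e6 s

own = predict.evaluate_account(model, held_out.delays)
base = predict.evaluate_account(null, held_out.delays)
print(f"held-out personal account, {own.n_events} delays:")
print(f"  class-CDF model: mean R^2 = {own.mean_r2:+.3f} (SD {own.sd_r2:.2f})")
print(f"  uniform null   : mean R^2 = {base.mean_r2:+.3f} (SD {base.sd_r2:.2f})")

hourly = predict.build_hourly_model(
    np.concatenate([f.delays for f in rest]),
    np.concatenate([f.preceding_hours for f in rest]), label="personal")
own_h = predict.evaluate_account(hourly, held_out.delays, held_out.preceding_hours)
print(f"  hour-conditioned model: mean R^2 = {own_h.mean_r2:+.3f}")

# The class CDF predicts far better than the uniform null; conditioning on
# the hour of the preceding event adds little, because delay and hour are
# close to independent.
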