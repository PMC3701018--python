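"""Generate a labelled synthetic cohort and look at its timing structure.

The simulator produces event streams with the statistical signatures of the
three account classes: heavy-tailed inter-event delays with class-distinct
exponents, class-distinct daily activity profiles, and (for bots) scheduled
or constant-rate behaviour.
"""

import numpy as np

from chronosig import synth
from chronosig.events import clock_features, compute_delays

cohort = synth.simulate_cohort(synth.default_class_specs(), n_accounts_per_class=5,
                               n_events=400, seed=7)

print(f"{len(cohort.streams)} accounts, {sum(len(s) for s in cohort.streams)} events")
for label in ("personal", "managed", "bot"):
    streams = [s for s in cohort.streams if s.label == label]
    delays = np.concatenate([compute_delays(s).delays for s in streams])
    hours = np.concatenate([clock_features(s).local_hour for s in streams])
    busiest = np.argmax(np.bincount(hours, minlength=24))
    print(f"{label:>9}: median delay {np.median(delays):7.0f} s, "
          f"p95 {np.percentile(delays, 95):8.0f} s, busiest local hour {busiest:2d}")

# The median/p95 spread shows the burstiness of the delay mixture; the
# busiest hour reflects each class's diurnal profile (personal peaks in the
# evening, managed in work hours, bots have no preference).
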