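"""Generate heterogeneous per-slot outpatient show probabilities.

Real no-show risk varies by patient and schedule; this emulates the
output of a patient-level logistic model by drawing one probability per
booked slot, with the intercept calibrated so the population mean show
probability is 0.80, then plugs them into a solvable configuration.
"""

import numpy as np

from radcap import NoShowModelSpec, baseline_config, generate_show_probabilities, solve

config = baseline_config(n_regular=8, n_overtime=2, n_extra=2, overbook_gap=4)
spec = NoShowModelSpec(target_mean=0.80)
probs = generate_show_probabilities(spec, config.schedule, np.random.default_rng(7))

flat = [p for row in probs for p in row]
print(f"slots: {len(flat)}, mean show prob: {np.mean(flat):.3f}, "
      f"range: [{min(flat):.3f}, {max(flat):.3f}]")
print("period 1 slot probabilities:", [round(p, 3) for p in probs[0]])

heterogeneous = solve(config.with_show_probs(probs))
homogeneous = solve(config)  # constant 0.8 per slot
print(f"\nexpected day cost, heterogeneous slots: US$ {heterogeneous.expected_day_cost:.2f}")
print(f"expected day cost, constant 0.8 slots:   US$ {homogeneous.expected_day_cost:.2f}")
# Slot-level heterogeneity changes the Poisson-binomial show distribution
# (same mean, smaller variance than a binomial), which shifts the value
# of overbooked slots and hence the optimal allocation's expected cost.
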