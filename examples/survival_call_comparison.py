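"""Compare the prognostic value of reference calls vs model calls.

The clinically interesting question for a predicted biomarker is whether
its calls separate survival curves as well as the reference (pathologist)
calls do.  Here one half of a simulated cohort carries reference calls
and the disjoint other half carries model calls corrupted with 15% flips;
each call source gets its own log-rank test on its own subjects.
Noisier calls should separate the curves less sharply (larger p).
"""

import numpy as np
import pandas as pd

import aiocnn as ac

cfg = ac.SyntheticConfig(n_samples=600, n_genes=64, n_blocks=8,
                         hazard_ratio=3.0, censoring_rate=0.2, seed=4)
cohort = ac.simulate_cohort(cfg)
labels = ac.simulate_survival(cohort.labels, cfg)

rng = np.random.default_rng(0)
half = len(labels) // 2
ref = labels.iloc[:half].copy()
mod = labels.iloc[half:].copy()

ref["group"] = np.where(ref["ki67"] == 1, "Ki67+", "Ki67-")
flips = rng.random(len(mod)) < 0.15
model_calls = np.where(flips, 1 - mod["ki67"].to_numpy(int),
                       mod["ki67"].to_numpy(int))
mod["group"] = np.where(model_calls == 1, "Ki67+", "Ki67-")

results = ac.compare_call_sources(ref, mod)
for source, res in results.items():
    print(f"{source:9s} calls: log-rank chi2 = {res.statistic:6.2f}, "
          f"p = {res.p_value:.2e}, groups {res.group_sizes}")

curve = ac.km_estimate(ref["survival_days"].to_numpy(float),
                       ref["event"].to_numpy(int))
print(f"\nreference-arm KM: survival at 1000 days = "
      f"{curve.survival_at(1000):.3f} ({curve.n_total} subjects)")
print("both sources separate the arms; the noisier model calls usually "
      "yield the weaker (larger) p value")
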