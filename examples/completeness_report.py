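"""Assembly completeness by annotation class.

Simulates an annotated 200 kb reference and an alignment-derived depth
track in which a randomly chosen 30% of features are absent from the
assembly (depth 0), then reports per-class capture at the 90% threshold.
"""

import numpy as np

from scaffcheck import SimConfig, completeness_report, coverage_bimodality, feature_coverage
from scaffcheck.pairs import DepthTrack
from scaffcheck.synthetic import simulate_annotation

refs = {"ref1": 200_000}
features = simulate_annotation(refs, SimConfig(seed=4), n_features=90)

rng = np.random.default_rng(4)
missing = set(rng.choice(len(features), size=27, replace=False))
runs, cursor = [], 0
for i, f in enumerate(sorted(features, key=lambda f: f.start)):
    if f.start > cursor:
        runs.append(("ref1", cursor, f.start, 2))
    runs.append(("ref1", f.start, f.end, 0 if i in missing else 2))
    cursor = f.end
runs.append(("ref1", cursor, 200_000, 2))
track = DepthTrack.from_runs(runs)

coverages = feature_coverage(track, features)
report = completeness_report(coverages, tau=0.90)
print(report.to_string(index=False, float_format=lambda x: f"{x:.1f}"))

hist, extreme = coverage_bimodality(coverages)
print(f"\ncovered-fraction histogram (10 bins): {hist.tolist()}")
print(f"fraction of elements at the extremes (<=0.1 or >=0.9): {extreme:.2f}")
print("\npct_captured_ge_tau is the percent of each class with >=90% of its "
      "bases covered by the assembly alignment; an extreme fraction near 1 "
      "reflects the all-or-nothing capture typical of collapsed repeats.")
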