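"""Fit the three diet quality indexes and the 0-100 standardized scale.

On one synthetic cohort: the theoretical index (fixed guideline weights),
the empirical index (varimax factors of the 61 food items, ridge-weighted
against the risk score), and the hybrid index (conceptual groups merged
where r > 0.5, standardized, ridge-weighted).  The hybrid index is then
recast onto the Healthy-Eating-Index-style 0-100 scale.
"""

import numpy as np

from likingdqi import (CohortSpec, DQIConfig, build_crfs, empirical_dqi,
                       generate_cohort, hybrid_dqi, standardize_hybrid,
                       theoretical_dqi)
from likingdqi.validation import Dataset

ds = Dataset.from_cohort(generate_cohort(CohortSpec(n=2000, seed=11)))
_, crfs = build_crfs(ds.biomarkers)
cov = ds.covariate_table()

theo = theoretical_dqi(ds.group_table())
emp = empirical_dqi(ds.survey, crfs, cov, DQIConfig(seed=11))
hyb = hybrid_dqi(ds.food_group_table(), crfs, cov, DQIConfig(seed=11))

print("Merged groups of the hybrid index:")
for name, members in hyb.merged_groups.items():
    if len(members) > 1:
        print(f"  {name}  <-  {', '.join(members)}")

print("\nHybrid ridge weights (reverse-coded: + = healthier liking), "
      f"penalty lambda = {hyb.lam:.2f}:")
for g, w in sorted(hyb.weights.items(), key=lambda kv: -abs(kv[1])):
    print(f"  {g:45s} {w:+.3f}")

print("\nCorrelations between indexes (training cohort):")
for a, b in [("theoretical", "empirical"), ("theoretical", "hybrid"),
             ("empirical", "hybrid")]:
    x = {"theoretical": theo, "empirical": emp, "hybrid": hyb}
    r = np.corrcoef(x[a].scores, x[b].scores)[0, 1]
    print(f"  {a} vs {b}: {r:.2f}")

scale = standardize_hybrid(hyb)
print("\n0-100 scoring standard derived from the hybrid weights:")
for comp in sorted(scale.components, key=lambda c: -scale.max_points[c]):
    role = "adequacy " if comp in scale.adequacy else "moderation"
    print(f"  {comp:45s} {role} max {scale.max_points[comp]:3d} pts")
scores100 = scale.score(ds.food_group_table())
print(f"\nCohort 0-100 scores: mean {scores100.mean():.1f}, "
      f"SD {scores100.std(ddof=1):.1f} (higher = lower predicted risk)")
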