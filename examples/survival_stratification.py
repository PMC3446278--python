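"""Split a cohort by enrichment status and compare survival.

Samples positively enriched for the module form group 1; everyone else
(including not-testable samples) forms group 0.  The group effect is
estimated with a Cox proportional-hazards fit and a log-rank test, and
Kaplan-Meier step curves are produced per group.  Here the generator
plants a true hazard ratio of 3 on the active samples, so the estimate
should land near 3.
"""

import math

from slea import (
    EnrichmentConfig,
    SyntheticConfig,
    modules_with_decoys,
    groups_from_enrichment,
    compare_survival,
    normalize_rows,
    run_slea,
    simulate_expression,
    simulate_survival,
)

config = SyntheticConfig(
    n_genes=2_000,
    n_samples=300,
    module_size=70,
    activity_model="two-group",
    activity_delta=2.0,
    active_fraction=0.3,
    log_hazard_ratio=math.log(3.0),
    seed=3,
)
matrix, truth = simulate_expression(config)
clinical = simulate_survival(truth, config)
modules = modules_with_decoys(truth, config, n_decoys=0)

result = run_slea(
    normalize_rows(matrix), modules, EnrichmentConfig(n_permutations=2_000, seed=4)
)
labels = groups_from_enrichment(result, "true_module")
comparison = compare_survival(clinical, labels)

print(f"group sizes: enriched n1={comparison.n1}, rest n0={comparison.n0}")
print(f"hazard ratio (enriched vs rest): {comparison.hazard_ratio:.2f} "
      f"[95% CI {comparison.hr_ci[0]:.2f}, {comparison.hr_ci[1]:.2f}]  (truth: 3.0)")
print(f"Cox Wald p = {comparison.wald_p:.2e}, log-rank p = {comparison.logrank_p:.2e}")
for group, curve in sorted(comparison.km_curves.items()):
    tail = curve["survival"].iloc[-1]
    print(f"KM group {group}: {len(curve)} step points, final survival {tail:.2f}")

# A hazard ratio near 3 with a small p-value means the enrichment call
# stratifies the cohort into a poor-prognosis and a better-prognosis group,
# recovering the effect planted in the simulation.
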