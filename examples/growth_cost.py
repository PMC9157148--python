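"""Maximum growth rate, Welch comparison, and growth cost per protein unit.

Simulates plate-reader OD curves (readings every 10 min) for a vector
control and two overexpression strains with equal growth-rate retardation
but different expression levels, estimates each well's maximum growth rate
(MGR) as the steepest sliding-window slope of ln OD, compares strains with
Welch's t-test, and converts retardation into a per-unit protein cost.
"""

import numpy as np

from yeastburden import (
    GrowthSimConfig,
    cost_per_unit,
    generate_growth_curve,
    max_growth_rate,
    welch_t_test,
)

STRAINS = {"vector": 0.35, "EGFP-op": 0.28, "moxGFP-op": 0.28}
PROTEIN_LEVEL = {"EGFP-op": 1.0, "moxGFP-op": 1.4}  # relative expression

mgr = {}
for k, (strain, rate) in enumerate(STRAINS.items()):
    estimates = []
    for rep in range(8):  # 8 biological replicates
        config = GrowthSimConfig(rate=rate, noise_sd=0.005,
                                 seed=1000 * k + rep)
        curve = generate_growth_curve(config, strain_id=strain)
        estimates.append(max_growth_rate(curve, blank=config.initial_od).mgr)
    mgr[strain] = np.array(estimates)
    print(f"{strain:10s} MGR = {mgr[strain].mean():.3f} "
          f"+/- {mgr[strain].std(ddof=1):.3f} /h (true {rate:.2f})")

for strain in ("EGFP-op", "moxGFP-op"):
    res = welch_t_test(mgr[strain], mgr["vector"])
    retardation = mgr["vector"].mean() - mgr[strain].mean()
    cost = cost_per_unit(mgr[strain].mean(), mgr["vector"].mean(),
                         PROTEIN_LEVEL[strain])
    print(f"{strain:10s} vs vector: Welch p = {res.p:.1e}, "
          f"retardation {retardation:.3f} /h, "
          f"cost/unit {cost:.4f}")

print(
    "\nEqual retardation at 1.4x the expression level gives a 1.4-fold "
    "lower per-unit cost: the higher-expressed protein is the less toxic one."
)
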