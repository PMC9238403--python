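"""RC_Bray: locating observed Bray-Curtis within an assembly null.

Simulates a dispersal-limited cohort (founder effects, almost no
migration), builds the metacommunity pool from the table, and shows the
observed dissimilarities sitting above nearly the entire null
distribution (RC_Bray -> +1).
"""

import numpy as np

from ecoassembly import (
    ScenarioTruth,
    generate_scenario,
    metacommunity_pools,
    null_assemble,
    rc_bray,
    recovery_constraints,
    select_pairs,
)

truth = ScenarioTruth.default("dispersal_limitation", seed=3)
table, tree, meta, _ = generate_scenario(truth)
pools = metacommunity_pools(table)

print("pool built from all 20 samples:")
print(f"  taxa with positive occupancy weight: {pools.n_available}")

rng = np.random.default_rng(0)
sim = null_assemble(n_taxa=12, n_individuals=2000, pools=pools, rng=rng)
print(f"  one null community: {int((sim > 0).sum())} taxa, {int(sim.sum())} reads\n")

pairs = select_pairs(meta, recovery_constraints(truth))
rcs = []
for pair in pairs.pairs[:10]:
    res = rc_bray(pair, table, pools, n_null=199, seed=3)
    rcs.append(res.rc)
    print(
        f"  {pair[0]}-{pair[1]}: observed BC = {res.bc_observed:.3f}, "
        f"RC_Bray = {res.rc:+.3f}"
    )
print(
    f"\nmedian RC_Bray = {np.median(rcs):+.2f}; values above +0.95 mean the\n"
    "pair is less similar than expected from random assembly with the\n"
    "observed richness and abundance — dispersal limitation plus drift."
)
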