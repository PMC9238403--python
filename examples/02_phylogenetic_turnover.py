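"""betaMNTD by hand and betaNTI against the tip-shuffle null.

First reproduces the hand-computable 3-taxon betaMNTD example, then runs
the full betaNTI null model on a simulated two-environment dataset and
shows that cross-environment pairs score above +2 (variable selection).
"""

import io

import numpy as np
from skbio import TreeNode

from ecoassembly import (
    PairConstraints,
    ScenarioTruth,
    beta_mntd,
    beta_nti_batch,
    generate_scenario,
    patristic_matrix,
    select_pairs,
)

# --- the toy example ----------------------------------------------------
tree = TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))
dmat = patristic_matrix(tree)
order = list(dmat.ids)
x = np.array([1.0 if t == "A" else 0.0 for t in order])  # only taxon A
y = np.array([0.5 if t in ("B", "C") else 0.0 for t in order])  # B and C

print(f"patristic d(A,C) = {dmat['A', 'C']:.1f} (path sums: 1+1+2)")
print(f"betaMNTD(x, y)   = {beta_mntd(x, y, dmat):.2f}")
print("  = 0.5 * [min(d(A,B), d(A,C)) + 0.5*d(B,A) + 0.5*d(C,A)]")
print("  = 0.5 * [2 + 0.5*2 + 0.5*4] = 2.5\n")

# --- betaNTI on a selection-structured community ------------------------
truth = ScenarioTruth.default("variable_selection", seed=2)
table, sim_tree, meta, _ = generate_scenario(truth)
pairs = select_pairs(
    meta, PairConstraints(patient_relation="different", ward_relation="different")
)
dmat = patristic_matrix(sim_tree).filter(table.taxon_ids)
results = beta_nti_batch(pairs, table, dmat, n_null=199, seed=2)
z = np.array([r.bnti for r in results if not r.degenerate])
print(f"cross-environment pairs: {len(z)}")
print(f"median betaNTI = {np.median(z):.2f}; fraction > +2: {np.mean(z > 2):.2f}")
print(
    "betaNTI > 2 means the two communities are phylogenetically less\n"
    "similar than the tip-shuffle null expects — divergent (variable)\n"
    "selection, here created by opposite trait-environment filters."
)
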