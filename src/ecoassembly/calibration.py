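"""Null-model self-calibration checks.

Both null models should, by construction, flag ~5% of pairs when fed
data generated by the very process they test against:

* betaNTI on communities whose taxa are assigned to tips at random (no
  phylogenetic structure) is approximately standard normal, so
  |betaNTI| > 2 should occur for ~4.6% of pairs.
* RC_Bray on pairs generated by the assembly null itself is
  approximately uniform on [-1, 1], so |RC| > 0.95 should occur for
  ~5% of pairs.

These functions generate such data and measure the realized fractions;
they are used by the acceptance checks and are handy diagnostics for
any change to the null algorithms.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .containers import CommunityTable
from .metrics import bray_curtis
from .pairs import PairSet
from .phylo import beta_nti_batch, patristic_matrix
from .raupcrick import MetacommunityPools, null_assemble
from .simulate import simulate_tree

__all__ = ["betanti_calibration", "rc_self_calibration"]


def betanti_calibration(
    seed: int,
    n_taxa: int = 100,
    n_samples: int = 25,
    richness: int = 30,
    reads: int = 1000,
    n_pairs: int = 200,
    n_null: int = 999,
) -> dict:
    """Fraction of |betaNTI| > 2 on phylogeny-free random communities.

    Each community draws ``richness`` taxa uniformly at random from the
    tree's tips (abundances multinomial-uniform), which is exactly the
    tip-shuffle null hypothesis, so the betaNTI z-scores should be
    close to standard normal.
    """
    tree = simulate_tree(n_taxa, seed)
    tips = [t.name for t in tree.tips()]
    rows = []
    for i in range(n_samples):
        rng = derive_rng(seed, "bnti-cal", str(i))
        taxa = rng.choice(n_taxa, richness, replace=False)
        v = np.zeros(n_taxa, dtype=np.int64)
        v[taxa] = 1
        v[taxa] += rng.multinomial(reads - richness, np.full(richness, 1.0 / richness))
        rows.append(v)
    sids = [f"C{i:03d}" for i in range(n_samples)]
    table = CommunityTable(data=pd.DataFrame(np.asarray(rows), index=sids, columns=tips))
    pairs = PairSet(pairs=[tuple(p) for p in list(combinations(sids, 2))[:n_pairs]])
    dmat = patristic_matrix(tree).filter(tips)
    results = beta_nti_batch(pairs, table, dmat, n_null=n_null, seed=seed)
    vals = np.array([r.bnti for r in results if not r.degenerate])
    return {
        "fraction_beyond_2": float(np.mean(np.abs(vals) > 2)),
        "n_pairs": int(vals.size),
        "values": vals,
    }


def rc_self_calibration(
    seed: int,
    n_taxa: int = 100,
    n_pairs: int = 200,
    n_null: int = 999,
    reads: int = 2000,
) -> dict:
    """Fraction of |RC_Bray| > 0.95 when the observed pair is itself null.

    Pool weights are heterogeneous (lognormal abundances, random
    occupancies); each "observed" pair is drawn by the same assembly
    procedure as the null replicates, so its Bray-Curtis rank within
    the null distribution is uniform and RC is uniform on [-1, 1].
    """
    pool_rng = derive_rng(seed, "rc-cal-pool")
    ab = np.exp(pool_rng.normal(0.0, 1.0, n_taxa))
    ab /= ab.sum()
    occ = pool_rng.integers(1, 21, n_taxa).astype(float)
    occ /= occ.sum()
    pools = MetacommunityPools(
        taxon_ids=[f"t{i:03d}" for i in range(n_taxa)],
        occurrence_weight=occ,
        abundance_weight=ab,
    )

    rcs = np.empty(n_pairs)
    for k in range(n_pairs):
        rng = derive_rng(seed, "rc-cal-pair", str(k))
        rx = int(rng.integers(15, 45))
        ry = int(rng.integers(15, 45))
        x = null_assemble(rx, reads, pools, rng)
        y = null_assemble(ry, reads, pools, rng)
        observed = bray_curtis(x, y)
        nulls = np.empty(n_null)
        for j in range(n_null):
            nulls[j] = bray_curtis(
                null_assemble(rx, reads, pools, rng),
                null_assemble(ry, reads, pools, rng),
            )
        below = int((nulls < observed - 1e-12).sum())
        ties = int((np.abs(nulls - observed) <= 1e-12).sum())
        rcs[k] = 2.0 * ((below + 0.5 * ties) / n_null - 0.5)
    return {
        "fraction_beyond_095": float(np.mean(np.abs(rcs) > 0.95)),
        "n_pairs": n_pairs,
        "values": rcs,
    }
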