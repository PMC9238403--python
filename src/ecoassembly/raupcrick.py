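"""Abundance-based Raup-Crick null model (RC_Bray).

For a sample pair, each null replicate assembles both communities from
the metacommunity pool under the observed constraints — the observed
richness (number of taxa, drawn without replacement with probability
proportional to occupancy) and the observed total abundance (individuals
placed with probability proportional to pooled relative abundance) — and
computes the Bray-Curtis dissimilarity of the simulated pair. The
observed Bray-Curtis is located within this null distribution:

    frac_below = (#(null < obs) + 0.5 * #(null == obs)) / n_null
    RC_Bray    = 2 * (frac_below - 0.5)            in [-1, 1].

RC_Bray > 0.95 means the pair is less similar than expected by chance
(dispersal limitation acting with drift); RC_Bray < -0.95 means more
similar than chance (homogenizing dispersal); |RC_Bray| <= 0.95 is
consistent with drift acting alone. RC is consulted only for pairs with
|betaNTI| <= 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import derive_rng
from .containers import CommunityTable
from .metrics import bray_curtis
from .pairs import PairSet

__all__ = [
    "MetacommunityPools",
    "metacommunity_pools",
    "null_assemble",
    "RCBrayResult",
    "rc_bray",
    "rc_bray_batch",
]


@dataclass
class MetacommunityPools:
    """Per-taxon weights of the regional species pool.

    occurrence_weight is proportional to the number of pool samples in
    which the taxon occurs (occupancy); abundance_weight to its mean
    relative abundance over the pool. Both sum to 1, and any taxon with
    positive abundance weight also has positive occurrence weight.
    """

    taxon_ids: list[str]
    occurrence_weight: np.ndarray
    abundance_weight: np.ndarray

    def __post_init__(self):
        for w in (self.occurrence_weight, self.abundance_weight):
            if (w < 0).any():
                raise ValueError("pool weights must be nonnegative")
        if not np.isclose(self.occurrence_weight.sum(), 1.0):
            raise ValueError("occurrence weights must sum to 1")
        if not np.isclose(self.abundance_weight.sum(), 1.0):
            raise ValueError("abundance weights must sum to 1")
        orphan = (self.abundance_weight > 0) & (self.occurrence_weight == 0)
        if orphan.any():
            raise ValueError("abundance-weight support must lie within occurrence support")

    @property
    def n_available(self) -> int:
        return int((self.occurrence_weight > 0).sum())


def metacommunity_pools(
    table: CommunityTable, sample_subset: list[str] | None = None
) -> MetacommunityPools:
    """Occupancy and mean-relative-abundance pool weights from a table.

    ``sample_subset`` restricts the pool (e.g. to one comparison group's
    parent cohort); default is every sample in the table.
    """
    sub = table if sample_subset is None else table.subset_samples(sample_subset)
    if sub.n_samples == 0:
        raise ValueError("empty sample subset for pool construction")
    a = sub.abundance
    occ = (a > 0).sum(axis=0).astype(float)
    row_tot = a.sum(axis=1, keepdims=True)
    if (row_tot == 0).any():
        raise ValueError("pool contains an all-zero sample")
    rel = a / row_tot
    ab = rel.mean(axis=0)
    if occ.sum() == 0:
        raise ValueError("pool has no occurrences")
    return MetacommunityPools(
        taxon_ids=sub.taxon_ids,
        occurrence_weight=occ / occ.sum(),
        abundance_weight=ab / ab.sum(),
    )


def null_assemble(
    n_taxa: int,
    n_individuals: int,
    pools: MetacommunityPools,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assemble one null community under richness and abundance constraints.

    Draws ``n_taxa`` distinct taxa without replacement with probability
    proportional to occupancy (via exponential first-arrival keys), seeds
    each with one individual, then distributes the remaining
    ``n_individuals - n_taxa`` individuals multinomially with probability
    proportional to abundance weight renormalized over the drawn set. The
    result sums to ``n_individuals`` with exactly ``n_taxa`` positive
    entries.
    """
    occ = pools.occurrence_weight
    avail = pools.n_available
    if not 1 <= n_taxa <= avail:
        raise ValueError(f"n_taxa={n_taxa} outside [1, {avail}] available pool taxa")
    if n_individuals < n_taxa:
        raise ValueError("n_individuals must be >= n_taxa")

    # exponential race: the n_taxa smallest Exp(1)/w keys are a weighted
    # sample without replacement proportional to w
    keys = np.full(occ.size, np.inf)
    pos = occ > 0
    keys[pos] = rng.exponential(size=int(pos.sum())) / occ[pos]
    chosen = np.argpartition(keys, n_taxa - 1)[:n_taxa]

    vec = np.zeros(occ.size, dtype=np.int64)
    vec[chosen] = 1
    remaining = n_individuals - n_taxa
    if remaining > 0:
        p = pools.abundance_weight[chosen]
        tot = p.sum()
        p = np.full(n_taxa, 1.0 / n_taxa) if tot == 0 else p / tot
        vec[chosen] += rng.multinomial(remaining, p)
    return vec


@dataclass
class RCBrayResult:
    """Observed Bray-Curtis located within its assembly-null distribution."""

    pair: tuple[str, str]
    bc_observed: float
    frac_below: float
    rc: float
    n_null: int


def rc_bray(
    pair: tuple[str, str],
    table: CommunityTable,
    pools: MetacommunityPools,
    n_null: int = 999,
    seed: int = 0,
) -> RCBrayResult:
    """RC_Bray for one sample pair.

    Each replicate assembles both members with their observed richness
    and observed (integer) total abundance, then compares Bray-Curtis
    values; ties between null and observed are half-weighted. The RNG
    stream is derived from ``(seed, sorted pair ids)``.
    """
    a, b = pair
    x = table.sample_vector(a)
    y = table.sample_vector(b)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("RC_Bray undefined for a zero-total sample")
    observed = bray_curtis(x, y)

    rx, ry = int((x > 0).sum()), int((y > 0).sum())
    nx, ny = int(round(x.sum())), int(round(y.sum()))
    lo, hi = sorted((a, b))
    rng = derive_rng(seed, "rc", lo, hi)

    nulls = np.empty(n_null)
    for k in range(n_null):
        sim_x = null_assemble(rx, nx, pools, rng)
        sim_y = null_assemble(ry, ny, pools, rng)
        nulls[k] = bray_curtis(sim_x, sim_y)

    below = int((nulls < observed - 1e-12).sum())
    ties = int((np.abs(nulls - observed) <= 1e-12).sum())
    frac_below = (below + 0.5 * ties) / n_null
    return RCBrayResult(
        pair=(a, b),
        bc_observed=observed,
        frac_below=frac_below,
        rc=2.0 * (frac_below - 0.5),
        n_null=n_null,
    )


def rc_bray_batch(
    pairs: PairSet,
    table: CommunityTable,
    pools: MetacommunityPools,
    n_null: int = 999,
    seed: int = 0,
) -> list[RCBrayResult]:
    """RC_Bray for every pair in a :class:`PairSet` (order-independent)."""
    missing = {s for p in pairs.pairs for s in p} - set(table.sample_ids)
    if missing:
        raise ValueError(f"pair member(s) missing from table: {sorted(missing)}")
    return [rc_bray(p, table, pools, n_null=n_null, seed=seed) for p in pairs.pairs]
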