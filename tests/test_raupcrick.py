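import numpy as np
import pandas as pd
import pytest

from ecoassembly.containers import CommunityTable
from ecoassembly.pairs import PairSet
from ecoassembly.raupcrick import (
    MetacommunityPools,
    metacommunity_pools,
    null_assemble,
    rc_bray,
    rc_bray_batch,
)


class TestMetacommunityPools:
    def test_occupancy_weights_from_counts(self):
        table = CommunityTable(
            data=pd.DataFrame(
                [[5, 1, 0], [5, 0, 0]], index=["S1", "S2"], columns=["a", "b", "c"]
            )
        )
        pools = metacommunity_pools(table)
        # taxon a occurs in 2 samples, b in 1, c in 0
        assert pools.occurrence_weight.tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert pools.abundance_weight[2] == 0.0

    def test_weights_sum_to_one(self, toy_table):
        pools = metacommunity_pools(toy_table)
        assert pools.occurrence_weight.sum() == pytest.approx(1.0)
        assert pools.abundance_weight.sum() == pytest.approx(1.0)

    def test_subset_restricts_pool(self, toy_table):
        pools = metacommunity_pools(toy_table, ["S1", "S2"])
        # t4 only occurs in S4/S5 -> zero weight in this pool
        idx = toy_table.taxon_ids.index("t4")
        assert pools.occurrence_weight[idx] == 0.0

    def test_empty_subset_rejected(self, toy_table):
        with pytest.raises(ValueError, match="empty"):
            metacommunity_pools(toy_table, [])

    def test_orphan_abundance_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            MetacommunityPools(
                taxon_ids=["a", "b"],
                occurrence_weight=np.array([1.0, 0.0]),
                abundance_weight=np.array([0.0, 1.0]),
            )


def uniform_pools(n=10):
    return MetacommunityPools(
        taxon_ids=[f"t{i}" for i in range(n)],
        occurrence_weight=np.full(n, 1 / n),
        abundance_weight=np.full(n, 1 / n),
    )


class TestNullAssemble:
    def test_sum_and_support(self, rng):
        pools = uniform_pools()
        v = null_assemble(4, 50, pools, rng)
        assert v.sum() == 50
        assert (v > 0).sum() == 4

    def test_individuals_equal_taxa_all_ones(self, rng):
        v = null_assemble(5, 5, uniform_pools(), rng)
        assert sorted(v[v > 0].tolist()) == [1] * 5

    def test_full_pool_draw_includes_everything(self, rng):
        v = null_assemble(10, 100, uniform_pools(10), rng)
        assert (v > 0).all()

    def test_oversized_richness_rejected(self, rng):
        with pytest.raises(ValueError, match="n_taxa"):
            null_assemble(11, 100, uniform_pools(10), rng)

    def test_too_few_individuals_rejected(self, rng):
        with pytest.raises(ValueError, match="n_individuals"):
            null_assemble(5, 4, uniform_pools(), rng)

    def test_inclusion_frequency_uniform_under_uniform_pool(self, rng):
        # exact inclusion probability of each taxon is n_taxa_drawn/n_pool
        pools = uniform_pools(10)
        reps = 4000
        hits = np.zeros(10)
        for _ in range(reps):
            hits += null_assemble(3, 10, pools, rng) > 0
        p = 3 / 10
        se = np.sqrt(p * (1 - p) / reps)
        assert np.all(np.abs(hits / reps - p) < 5 * se)


class TestRCBray:
    def test_observed_above_every_null_gives_plus_one(self, rng):
        # pair on two disjoint taxa; the pool only ever assembles taxon a,
        # so every null pair is identical (BC 0) while the observed BC is 1
        pools = MetacommunityPools(
            taxon_ids=["a", "b"],
            occurrence_weight=np.array([1.0, 0.0]),
            abundance_weight=np.array([1.0, 0.0]),
        )
        table = CommunityTable(
            data=pd.DataFrame([[10, 0], [0, 10]], index=["S1", "S2"], columns=["a", "b"])
        )
        res = rc_bray(("S1", "S2"), table, pools, n_null=99, seed=0)
        assert res.bc_observed == 1.0
        assert res.rc == 1.0

    def test_observed_below_every_null_gives_minus_one(self):
        # identical observed pair (BC 0) against a pool spread over many taxa
        n = 20
        ids = [f"t{i}" for i in range(n)]
        pools = MetacommunityPools(
            taxon_ids=ids,
            occurrence_weight=np.full(n, 1 / n),
            abundance_weight=np.full(n, 1 / n),
        )
        row = np.zeros(n, dtype=int)
        row[:3] = [5, 3, 2]
        table = CommunityTable(
            data=pd.DataFrame([row, row], index=["S1", "S2"], columns=ids)
        )
        res = rc_bray(("S1", "S2"), table, pools, n_null=99, seed=1)
        assert res.bc_observed == 0.0
        assert res.rc == -1.0

    def test_all_ties_give_zero(self):
        # single-taxon pool: every assembly is identical to the observed pair
        pools = MetacommunityPools(
            taxon_ids=["a"],
            occurrence_weight=np.array([1.0]),
            abundance_weight=np.array([1.0]),
        )
        table = CommunityTable(
            data=pd.DataFrame([[10], [10]], index=["S1", "S2"], columns=["a"])
        )
        res = rc_bray(("S1", "S2"), table, pools, n_null=99, seed=0)
        assert res.frac_below == pytest.approx(0.5)
        assert res.rc == pytest.approx(0.0)

    def test_rc_consistent_with_frac_below(self, toy_table):
        pools = metacommunity_pools(toy_table)
        res = rc_bray(("S1", "S2"), toy_table, pools, n_null=199, seed=5)
        assert res.rc == pytest.approx(2 * (res.frac_below - 0.5))
        assert -1.0 <= res.rc <= 1.0

    def test_deterministic_and_order_invariant(self, toy_table):
        pools = metacommunity_pools(toy_table)
        pairs = PairSet(pairs=[("S1", "S2"), ("S2", "S4")])
        rev = PairSet(pairs=pairs.pairs[::-1])
        a = {r.pair: r.rc for r in rc_bray_batch(pairs, toy_table, pools, 99, seed=9)}
        b = {r.pair: r.rc for r in rc_bray_batch(rev, toy_table, pools, 99, seed=9)}
        assert a == b

    def test_two_seeds_agree_within_monte_carlo_error(self, toy_table):
        pools = metacommunity_pools(toy_table)
        r1 = rc_bray(("S1", "S4"), toy_table, pools, n_null=999, seed=1).rc
        r2 = rc_bray(("S1", "S4"), toy_table, pools, n_null=999, seed=2).rc
        assert abs(r1 - r2) < 0.15
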