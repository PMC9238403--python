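import io

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

from ecoassembly.containers import CommunityTable
from ecoassembly.pairs import PairSet
from ecoassembly.phylo import beta_mntd, beta_nti, beta_nti_batch, patristic_matrix


def brute_force_bmntd(x, y, d, weighted=True):
    """Independent double-loop reference implementation."""
    ix = [i for i, v in enumerate(x) if v > 0]
    iy = [j for j, v in enumerate(y) if v > 0]
    fx = [x[i] / sum(x[i] for i in ix) for i in ix] if weighted else [1 / len(ix)] * len(ix)
    fy = [y[j] / sum(y[j] for j in iy) for j in iy] if weighted else [1 / len(iy)] * len(iy)
    a = sum(f * min(d[i][j] for j in iy) for f, i in zip(fx, ix))
    b = sum(f * min(d[i][j] for i in ix) for f, j in zip(fy, iy))
    return 0.5 * (a + b)


class TestPatristicMatrix:
    def test_cherry(self):
        tree = TreeNode.read(io.StringIO("(A:1,B:1);"))
        dm = patristic_matrix(tree)
        assert dm["A", "B"] == 2.0

    def test_three_taxon_path_sums(self, three_taxon_tree):
        dm = patristic_matrix(three_taxon_tree)
        assert dm["A", "C"] == 4.0
        assert dm["B", "C"] == 4.0
        assert dm["A", "B"] == 2.0

    def test_zero_diagonal(self, three_taxon_tree):
        dm = patristic_matrix(three_taxon_tree)
        assert np.allclose(np.diag(dm.data), 0.0)


class TestBetaMNTD:
    def test_identical_communities_zero(self, three_taxon_tree):
        dm = patristic_matrix(three_taxon_tree)
        x = np.array([0.2, 0.3, 0.5])
        assert beta_mntd(x, x, dm) == 0.0

    def test_hand_computed_toy(self, three_taxon_tree):
        dm = patristic_matrix(three_taxon_tree)
        order = list(dm.ids)
        x = np.array([1.0 if t == "A" else 0.0 for t in order])
        y = np.array([0.5 if t in ("B", "C") else 0.0 for t in order])
        # 0.5 * [min d(A,-) over {B,C} + 0.5 d(B,A) + 0.5 d(C,A)] = 2.5
        assert beta_mntd(x, y, dm) == pytest.approx(2.5, abs=1e-12)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_on_random_instances(self, rng, weighted):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            cond = rng.random((n, n))
            d = (cond + cond.T) / 2
            np.fill_diagonal(d, 0.0)
            dm = DistanceMatrix(d, ids=[f"t{i}" for i in range(n)])
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if x.sum() == 0 or y.sum() == 0:
                continue
            got = beta_mntd(x, y, dm, weighted=weighted)
            want = brute_force_bmntd(x.tolist(), y.tolist(), d.tolist(), weighted)
            assert got == pytest.approx(want, abs=1e-12)

    def test_symmetric_and_abundance_scale_invariant(self, three_taxon_tree, rng):
        dm = patristic_matrix(three_taxon_tree)
        x = rng.random(3) + 0.1
        y = rng.random(3) + 0.1
        assert beta_mntd(x, y, dm) == pytest.approx(beta_mntd(y, x, dm))
        assert beta_mntd(5.0 * x, y, dm) == pytest.approx(beta_mntd(x, y, dm))

    def test_branch_scaling_multiplies_result(self, three_taxon_tree, rng):
        dm = patristic_matrix(three_taxon_tree)
        scaled = DistanceMatrix(dm.data * 3.0, ids=dm.ids)
        x = rng.random(3) + 0.1
        y = np.array([1.0, 0.0, 2.0])
        assert beta_mntd(x, y, scaled) == pytest.approx(3.0 * beta_mntd(x, y, dm))

    def test_empty_community_rejected(self, three_taxon_tree):
        dm = patristic_matrix(three_taxon_tree)
        with pytest.raises(ValueError, match="empty community"):
            beta_mntd([0, 0, 0], [1, 0, 0], dm)


def small_table_and_dmat(seed=0, n_taxa=12, n_samples=4, reads=100):
    rng = np.random.default_rng(seed)
    cond = rng.random((n_taxa, n_taxa)) + 0.1
    d = (cond + cond.T) / 2
    np.fill_diagonal(d, 0.0)
    ids = [f"t{i:02d}" for i in range(n_taxa)]
    dmat = DistanceMatrix(d, ids=ids)
    rows = []
    for _ in range(n_samples):  # sparse supports so the tip-shuffle null has spread
        taxa = rng.choice(n_taxa, 5, replace=False)
        v = np.zeros(n_taxa, dtype=np.int64)
        v[taxa] = rng.multinomial(reads, np.full(5, 0.2)) + 1
        rows.append(v)
    sids = [f"S{i}" for i in range(n_samples)]
    table = CommunityTable(data=pd.DataFrame(rows, index=sids, columns=ids))
    return table, dmat


class TestBetaNTI:
    def test_null_mean_match_gives_zero_z(self):
        # a symmetric distance matrix where every permutation yields the
        # same betaMNTD is degenerate; instead check the z-score formula
        table, dmat = small_table_and_dmat()
        res = beta_nti(("S0", "S1"), table, dmat, n_null=99, seed=0)
        assert res.bnti == pytest.approx(
            (res.bmntd_observed - res.null_mean) / res.null_sd
        )

    def test_single_shared_taxon_degenerate(self):
        ids = ["a", "b"]
        dmat = DistanceMatrix([[0, 1], [1, 0]], ids=ids)
        table = CommunityTable(
            data=pd.DataFrame([[5, 0], [3, 0]], index=["S1", "S2"], columns=ids)
        )
        res = beta_nti(("S1", "S2"), table, dmat, n_null=99, seed=0)
        assert res.degenerate
        assert np.isnan(res.bnti)

    def test_deterministic_given_seed(self):
        table, dmat = small_table_and_dmat()
        a = beta_nti(("S0", "S1"), table, dmat, n_null=199, seed=42)
        b = beta_nti(("S0", "S1"), table, dmat, n_null=199, seed=42)
        assert a == b

    def test_small_n_null_rejected(self):
        table, dmat = small_table_and_dmat()
        with pytest.raises(ValueError, match="99"):
            beta_nti(("S0", "S1"), table, dmat, n_null=50, seed=0)

    def test_batch_order_invariance(self):
        table, dmat = small_table_and_dmat()
        pairs_fwd = PairSet(pairs=[("S0", "S1"), ("S2", "S3"), ("S1", "S2")])
        pairs_rev = PairSet(pairs=pairs_fwd.pairs[::-1])
        fwd = {r.pair: r.bnti for r in beta_nti_batch(pairs_fwd, table, dmat, 99, seed=7)}
        rev = {r.pair: r.bnti for r in beta_nti_batch(pairs_rev, table, dmat, 99, seed=7)}
        assert fwd == rev

    def test_batch_of_one_equals_single_call(self):
        table, dmat = small_table_and_dmat()
        single = beta_nti(("S1", "S3"), table, dmat, n_null=99, seed=3)
        batch = beta_nti_batch(PairSet(pairs=[("S1", "S3")]), table, dmat, 99, seed=3)
        assert batch[0] == single

    def test_missing_sample_named(self):
        table, dmat = small_table_and_dmat()
        with pytest.raises(ValueError, match="S9"):
            beta_nti_batch(PairSet(pairs=[("S0", "S9")]), table, dmat, 99, seed=0)
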