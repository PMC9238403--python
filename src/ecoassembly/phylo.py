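"""Phylogenetic turnover null model: betaMNTD and betaNTI.

The beta mean nearest-taxon distance between communities x and y over a
patristic distance matrix d is

    betaMNTD(x, y) = 0.5 * [ sum_{i in x} f_ix * min_{j in y} d(i, j)
                           + sum_{j in y} f_jy * min_{i in x} d(i, j) ],

with f the within-sample relative abundances over the taxa present
(abundance-weighted mode) or 1/richness (unweighted mode). The beta
nearest-taxon index (betaNTI) is the z-score of the observed betaMNTD
against a null distribution obtained by shuffling taxon labels across the
tips of the distance matrix — i.e. permuting rows/columns of the
patristic matrix over the full taxon pool of the analyzed table — and
recomputing betaMNTD. |betaNTI| > 2 indicates deterministic selection:
variable selection when positive (communities phylogenetically less
similar than chance), homogenizing selection when negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode

from ._rng import derive_rng
from .containers import CommunityTable
from .pairs import PairSet

__all__ = [
    "patristic_matrix",
    "beta_mntd",
    "BetaNTIResult",
    "beta_nti",
    "beta_nti_batch",
]


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip patristic distances (sum of branch lengths on the path)."""
    for tip in tree.tips():
        if tip.name is None:
            raise ValueError("tree has an unlabeled tip")
    return tree.tip_tip_distances()


def _present(v: np.ndarray) -> np.ndarray:
    idx = np.flatnonzero(v > 0)
    if idx.size == 0:
        raise ValueError("empty community: no taxa with positive abundance")
    return idx


def _bmntd_indexed(
    d: np.ndarray,
    ix: np.ndarray,
    iy: np.ndarray,
    fx: np.ndarray,
    fy: np.ndarray,
) -> float:
    sub = d[np.ix_(ix, iy)]
    return 0.5 * (fx @ sub.min(axis=1) + fy @ sub.min(axis=0))


def _weights(v: np.ndarray, idx: np.ndarray, weighted: bool) -> np.ndarray:
    if weighted:
        w = v[idx].astype(float)
        return w / w.sum()
    return np.full(idx.size, 1.0 / idx.size)


def beta_mntd(x, y, dmat: DistanceMatrix, weighted: bool = True) -> float:
    """Between-community mean nearest-taxon distance.

    Parameters
    ----------
    x, y : array-like
        Abundance vectors aligned with ``dmat.ids``; each must have a
        positive total.
    dmat : skbio.DistanceMatrix
        Patristic distances between taxa.
    weighted : bool
        Abundance-weighted (default) or presence/absence (1/richness).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(dmat.ids)
    if x.shape != (n,) or y.shape != (n,):
        raise ValueError("abundance vectors must align with the distance matrix labels")
    ix, iy = _present(x), _present(y)
    fx = _weights(x, ix, weighted)
    fy = _weights(y, iy, weighted)
    return float(_bmntd_indexed(dmat.data, ix, iy, fx, fy))


@dataclass
class BetaNTIResult:
    """Observed betaMNTD, its tip-shuffle null moments, and the z-score."""

    pair: tuple[str, str]
    bmntd_observed: float
    null_mean: float
    null_sd: float
    bnti: float  # NaN when degenerate
    n_null: int
    degenerate: bool


def _beta_nti_core(
    x: np.ndarray,
    y: np.ndarray,
    d: np.ndarray,
    n_null: int,
    rng: np.random.Generator,
    weighted: bool,
    pair: tuple[str, str],
) -> BetaNTIResult:
    n = d.shape[0]
    ix, iy = _present(x), _present(y)
    fx = _weights(x, ix, weighted)
    fy = _weights(y, iy, weighted)
    observed = _bmntd_indexed(d, ix, iy, fx, fy)

    nulls = np.empty(n_null)
    for k in range(n_null):
        perm = rng.permutation(n)
        nulls[k] = _bmntd_indexed(d, perm[ix], perm[iy], fx, fy)
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1))
    degenerate = null_sd == 0.0
    bnti = math.nan if degenerate else (observed - null_mean) / null_sd
    return BetaNTIResult(
        pair=pair,
        bmntd_observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        bnti=float(bnti),
        n_null=n_null,
        degenerate=degenerate,
    )


def beta_nti(
    pair: tuple[str, str],
    table: CommunityTable,
    dmat: DistanceMatrix,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> BetaNTIResult:
    """betaNTI for one sample pair.

    The null shuffles taxon labels across the full taxon pool of the
    table (``taxa.labels``-style randomization). Requires ``n_null >= 99``
    for a stable z-score. Pairs whose null distribution has zero spread
    (e.g. both samples reduced to the same single taxon) are flagged
    ``degenerate`` with ``bnti = NaN`` rather than coerced to 0.

    The RNG stream is derived from ``(seed, sorted pair ids)``, so batch
    order and parallel execution cannot change any per-pair result.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99 for a stable z-score")
    a, b = pair
    taxa = list(dmat.ids)
    if table.taxon_ids != taxa:
        raise ValueError("table taxa must align with distance-matrix labels")
    lo, hi = sorted((a, b))
    rng = derive_rng(seed, "bnti", lo, hi)
    return _beta_nti_core(
        table.sample_vector(a),
        table.sample_vector(b),
        dmat.data,
        n_null,
        rng,
        weighted,
        (a, b),
    )


def beta_nti_batch(
    pairs: PairSet,
    table: CommunityTable,
    dmat: DistanceMatrix,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> list[BetaNTIResult]:
    """betaNTI for every pair in a :class:`PairSet`.

    Per-pair RNG streams are derived deterministically from
    ``(seed, pair ids)``; results are independent of pair order.
    """
    missing = {s for p in pairs.pairs for s in p} - set(table.sample_ids)
    if missing:
        raise ValueError(f"pair member(s) missing from table: {sorted(missing)}")
    return [
        beta_nti(p, table, dmat, n_null=n_null, seed=seed, weighted=weighted)
        for p in pairs.pairs
    ]
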