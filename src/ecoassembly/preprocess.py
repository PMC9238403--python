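"""Preprocessing applied before any null model.

Order matters and follows standard amplicon practice: rarefy counts to an
even depth first, then apply the prevalence filter (taxa seen in fewer
than ``min_samples`` samples are dropped). Absolute-abundance scaling
(quantitative microbiome profiling) is an alternative mode that converts
relative proportions into copies per gram using per-sample qPCR loads and
optional per-taxon 16S copy numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .containers import CommunityTable

__all__ = ["rarefy", "prevalence_filter", "to_absolute"]


def rarefy(
    table: CommunityTable,
    depth: int,
    seed: int,
) -> tuple[CommunityTable, list[str]]:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped and returned in the
    report list. A sample whose total equals ``depth`` is returned
    unchanged (all of its reads are kept). Deterministic given ``seed``;
    each sample uses an independent stream keyed by its id, so the result
    does not depend on sample order.

    Returns
    -------
    (CommunityTable, list of str)
        The rarefied table and the ids of dropped samples.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    if table.is_absolute:
        raise ValueError("rarefaction applies to raw integer counts, not absolute abundances")
    counts = table.data.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefaction requires integer counts")
    counts = counts.astype(np.int64)

    kept_rows = []
    kept_ids = []
    dropped = []
    for i, sid in enumerate(table.sample_ids):
        total = int(counts[i].sum())
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            kept_rows.append(counts[i])
        else:
            rng = derive_rng(seed, "rarefy", sid)
            kept_rows.append(rng.multivariate_hypergeometric(counts[i], depth))
        kept_ids.append(sid)
    if not kept_ids:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    data = pd.DataFrame(np.asarray(kept_rows), index=kept_ids, columns=table.taxon_ids)
    data.index.name = table.data.index.name
    return replace(table, data=data), dropped


def prevalence_filter(table: CommunityTable, min_samples: int) -> CommunityTable:
    """Drop taxa present (abundance > 0) in fewer than ``min_samples`` samples.

    The boundary is strict: a taxon occurring in exactly ``min_samples``
    samples is retained.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be a positive integer")
    occupancy = (table.data.to_numpy() > 0).sum(axis=0)
    keep = occupancy >= min_samples
    if not keep.any():
        warnings.warn("prevalence filter removed every taxon", stacklevel=2)
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    return table.subset_taxa(kept)


def to_absolute(
    table: CommunityTable,
    loads: dict[str, float],
    copy_numbers: dict[str, float] | None = None,
) -> CommunityTable:
    """Scale counts to absolute abundances (quantitative profiling).

    Each count is divided by its taxon's 16S copy number (gene copies ->
    genome equivalents), rows are renormalized to proportions, and each
    row is multiplied by that sample's total load. Row sums of the output
    equal the supplied loads. Taxa missing from ``copy_numbers`` default
    to 1 with a warning, so the correction degrades gracefully to pure
    load scaling.
    """
    missing = [s for s in table.sample_ids if s not in loads]
    if missing:
        raise ValueError(f"missing load for sample(s): {missing}")
    load_vec = np.array([loads[s] for s in table.sample_ids], dtype=float)
    if (load_vec <= 0).any():
        bad = [s for s, v in zip(table.sample_ids, load_vec) if v <= 0]
        raise ValueError(f"loads must be positive; offending sample(s): {bad}")

    if copy_numbers:
        absent = [t for t in table.taxon_ids if t not in copy_numbers]
        if absent:
            warnings.warn(
                f"{len(absent)} taxa lack a copy number; defaulting to 1",
                stacklevel=2,
            )
        cn = np.array([copy_numbers.get(t, 1.0) for t in table.taxon_ids], dtype=float)
        if (cn <= 0).any():
            raise ValueError("copy numbers must be positive")
    else:
        cn = np.ones(table.n_taxa)

    genome_eq = table.data.to_numpy(dtype=float) / cn
    row_tot = genome_eq.sum(axis=1, keepdims=True)
    if (row_tot == 0).any():
        empty = [s for s, t in zip(table.sample_ids, row_tot.ravel()) if t == 0]
        raise ValueError(f"cannot scale all-zero sample(s): {empty}")
    scaled = genome_eq / row_tot * load_vec[:, None]
    data = pd.DataFrame(scaled, index=table.data.index, columns=table.data.columns)
    return CommunityTable(data=data, is_absolute=True)
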