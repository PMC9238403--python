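"""Compositional turnover metrics: Bray-Curtis, richness, and the
within-patient longitudinal dissimilarity series.

Bray-Curtis between abundance vectors x and y is

    BC(x, y) = sum_i |x_i - y_i| / sum_i (x_i + y_i),

bounded in [0, 1], with 0 for identical compositions and 1 for disjoint
supports. The longitudinal summaries order each patient's samples by day
of life and report either adjacent-pair dissimilarities (community
turnover between consecutive visits) or every later sample's
dissimilarity to the patient's first ("founder") sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CommunityTable

__all__ = [
    "bray_curtis",
    "bray_curtis_matrix",
    "richness",
    "DissimilaritySeries",
    "adjacent_dissimilarity",
    "to_founder_dissimilarity",
]


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity between two nonnegative abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(table: CommunityTable) -> pd.DataFrame:
    """Full pairwise Bray-Curtis matrix (export only, not analyzed further)."""
    a = table.abundance
    n = table.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(a[i], a[j])
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)


def richness(x) -> int:
    """Observed richness: number of taxa with abundance > 0."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    return int((x > 0).sum())


@dataclass
class DissimilaritySeries:
    """Ordered per-patient dissimilarity values (one per later timepoint)."""

    patient_id: str
    timepoints: list[int] = field(default_factory=list)  # day_of_life of the later sample
    values: list[float] = field(default_factory=list)


def _patient_order(table: CommunityTable, meta: pd.DataFrame):
    """Yield (patient_id, [sample_ids ordered by day_of_life]) for samples in the table."""
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    for pid, sub in meta.groupby("patient_id", sort=True):
        days = sub["day_of_life"]
        if days.duplicated().any():
            raise ValueError(
                f"patient {pid!r} has tied day_of_life values; ordering ambiguous"
            )
        yield str(pid), sub.sort_values("day_of_life")


def adjacent_dissimilarity(
    table: CommunityTable, meta: pd.DataFrame
) -> list[DissimilaritySeries]:
    """Bray-Curtis between consecutive samples of each patient.

    Patients with a single sample are skipped with a warning. A patient
    with samples at n timepoints contributes n - 1 values.
    """
    out = []
    for pid, sub in _patient_order(table, meta):
        if len(sub) < 2:
            warnings.warn(f"patient {pid!r} has <2 samples; skipped", stacklevel=2)
            continue
        series = DissimilaritySeries(patient_id=pid)
        sids = list(sub["sample_id"])
        days = list(sub["day_of_life"])
        for k in range(1, len(sids)):
            series.timepoints.append(int(days[k]))
            series.values.append(
                bray_curtis(table.sample_vector(sids[k - 1]), table.sample_vector(sids[k]))
            )
        out.append(series)
    return out


def to_founder_dissimilarity(
    table: CommunityTable, meta: pd.DataFrame
) -> list[DissimilaritySeries]:
    """Bray-Curtis between each patient's first sample and all later ones."""
    out = []
    for pid, sub in _patient_order(table, meta):
        if len(sub) < 2:
            warnings.warn(f"patient {pid!r} has <2 samples; skipped", stacklevel=2)
            continue
        series = DissimilaritySeries(patient_id=pid)
        sids = list(sub["sample_id"])
        days = list(sub["day_of_life"])
        founder = table.sample_vector(sids[0])
        for k in range(1, len(sids)):
            series.timepoints.append(int(days[k]))
            series.values.append(bray_curtis(founder, table.sample_vector(sids[k])))
        out.append(series)
    return out
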