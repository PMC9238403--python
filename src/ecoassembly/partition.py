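"""Five-way ecological-process classification and aggregation.

Each non-degenerate sample pair receives exactly one label from the
(betaNTI, RC_Bray) decision rule:

    betaNTI >  2                      -> variable_selection
    betaNTI < -2                      -> homogenizing_selection
    |betaNTI| <= 2 and RC >  0.95     -> dispersal_limitation_drift
    |betaNTI| <= 2 and RC < -0.95     -> homogenizing_dispersal
    otherwise                         -> drift

All thresholds are strict; values exactly at +-2 or +-0.95 fall to the
stochastic side. Per-group label counts are normalized into process
fractions; degenerate pairs (zero-spread betaNTI null) are excluded from
fractions and surfaced in a QC count. Pairs with betaNTI > 2 can be
regressed on absolute pairwise differences of a numeric covariate (e.g.
days postconception) to probe what drives variable selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProcessLabel",
    "classify_pair",
    "AssemblyProfile",
    "aggregate_profile",
    "DriverRegression",
    "driver_regression",
]

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


class ProcessLabel(str, Enum):
    VARIABLE_SELECTION = "variable_selection"
    HOMOGENIZING_SELECTION = "homogenizing_selection"
    DISPERSAL_LIMITATION_DRIFT = "dispersal_limitation_drift"
    HOMOGENIZING_DISPERSAL = "homogenizing_dispersal"
    DRIFT = "drift"


def classify_pair(bnti: float, rc: float | None = None) -> ProcessLabel:
    """Assign the ecological process label for one pair.

    ``rc`` is only consulted (and only required) when |betaNTI| <= 2.
    """
    if bnti is None or math.isnan(bnti):
        raise ValueError("betaNTI is missing; degenerate pairs cannot be classified")
    if bnti > BNTI_THRESHOLD:
        return ProcessLabel.VARIABLE_SELECTION
    if bnti < -BNTI_THRESHOLD:
        return ProcessLabel.HOMOGENIZING_SELECTION
    if rc is None or (isinstance(rc, float) and math.isnan(rc)):
        raise ValueError("RC_Bray required when |betaNTI| <= 2")
    if rc > RC_THRESHOLD:
        return ProcessLabel.DISPERSAL_LIMITATION_DRIFT
    if rc < -RC_THRESHOLD:
        return ProcessLabel.HOMOGENIZING_DISPERSAL
    return ProcessLabel.DRIFT


@dataclass
class AssemblyProfile:
    """Per-group fractions of the five process labels."""

    group_label: str
    fractions: dict[ProcessLabel, float]
    n_pairs: int
    n_degenerate: int = 0

    def __post_init__(self):
        if self.n_pairs > 0 and not math.isclose(
            sum(self.fractions.values()), 1.0, abs_tol=1e-9
        ):
            raise ValueError("process fractions must sum to 1")


def aggregate_profile(results: pd.DataFrame, grouping: str = "group") -> list[AssemblyProfile]:
    """Aggregate classified pairs into per-group process fractions.

    ``results`` needs columns ``bnti``, ``rc`` (NaN allowed where
    unused), ``degenerate`` (bool) and the grouping column. Degenerate
    pairs are excluded from fractions but counted per group. The
    output is invariant to row order and to duplicated rows being
    deduplicated beforehand.
    """
    profiles = []
    for group, sub in results.groupby(grouping, sort=True):
        degen = int(sub["degenerate"].sum()) if "degenerate" in sub else 0
        valid = sub[~sub["degenerate"]] if "degenerate" in sub else sub
        if len(valid) == 0:
            warnings.warn(f"group {group!r} has no classifiable pairs; omitted", stacklevel=2)
            continue
        labels = [
            classify_pair(row.bnti, getattr(row, "rc", None))
            for row in valid.itertuples()
        ]
        counts = {lab: 0 for lab in ProcessLabel}
        for lab in labels:
            counts[lab] += 1
        n = len(labels)
        profiles.append(
            AssemblyProfile(
                group_label=str(group),
                fractions={lab: c / n for lab, c in counts.items()},
                n_pairs=n,
                n_degenerate=degen,
            )
        )
    return profiles


@dataclass
class DriverRegression:
    """OLS of supra-threshold betaNTI on |covariate difference|."""

    covariate: str
    slope: float
    intercept: float
    r: float
    p_value: float
    n_pairs: int


def driver_regression(
    results: pd.DataFrame,
    meta: pd.DataFrame,
    covariate: str,
) -> DriverRegression:
    """Regress betaNTI > 2 values on absolute pairwise covariate differences.

    ``results`` needs columns ``sample_a``, ``sample_b``, ``bnti``. Only
    pairs with betaNTI strictly above 2 enter; both members must have a
    numeric covariate value. Returns the OLS slope with Pearson R and its
    p-value.
    """
    if covariate not in meta.columns:
        raise ValueError(f"covariate {covariate!r} not in metadata")
    sel = results[results["bnti"] > BNTI_THRESHOLD]
    vals = meta[covariate]
    diffs, ys = [], []
    for row in sel.itertuples():
        va, vb = vals.get(row.sample_a), vals.get(row.sample_b)
        if va is None or vb is None or pd.isna(va) or pd.isna(vb):
            continue
        diffs.append(abs(float(va) - float(vb)))
        ys.append(float(row.bnti))
    if len(diffs) < 3:
        raise ValueError("need >= 3 pairs with betaNTI > 2 and covariate values")
    diffs = np.asarray(diffs)
    ys = np.asarray(ys)
    if np.ptp(diffs) == 0:
        raise ValueError("constant covariate differences; correlation undefined")
    fit = stats.linregress(diffs, ys)
    return DriverRegression(
        covariate=covariate,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n_pairs=len(diffs),
    )
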