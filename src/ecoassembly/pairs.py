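"""Constrained sample-pair construction.

The null models are only meaningful over comparable sample pairs; the
pipeline's canonical comparisons are between different patients sampled
during the same calendar week, either within one clinical ward or across
two wards, plus founder-versus-later timepoint comparisons. Constraints
are declared with :class:`PairConstraints` and materialized into a
:class:`PairSet` of unordered, lexicographically sorted pairs, each
carrying a group label used for aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

__all__ = ["PairConstraints", "PairSet", "select_pairs", "founder_pairs"]


@dataclass(frozen=True)
class PairConstraints:
    """Predicate over unordered sample pairs.

    patient_relation : {"different", "same", "any"}
    ward_relation : {"same", "different", "any"} or a (ward_a, ward_b) tuple
        restricting to pairs with exactly those two (distinct) wards.
    time_matching : {"same_calendar_week", "same_day_of_life", "any"} or
        ("fixed", t1, t2) restricting to pairs with day_of_life {t1, t2}.
    """

    patient_relation: str = "different"
    ward_relation: object = "any"
    time_matching: object = "any"

    def __post_init__(self):
        if self.patient_relation not in ("different", "same", "any"):
            raise ValueError(f"bad patient_relation: {self.patient_relation!r}")
        wr = self.ward_relation
        if not (wr in ("same", "different", "any") or (isinstance(wr, tuple) and len(wr) == 2)):
            raise ValueError(f"bad ward_relation: {wr!r}")
        tm = self.time_matching
        ok = tm in ("same_calendar_week", "same_day_of_life", "any") or (
            isinstance(tm, tuple) and len(tm) == 3 and tm[0] == "fixed"
        )
        if not ok:
            raise ValueError(f"bad time_matching: {tm!r}")
        if (
            self.patient_relation == "any"
            and wr == "any"
            and tm == "any"
        ):
            raise ValueError("at least one pair constraint must be active")


@dataclass
class PairSet:
    """Unordered sample pairs with a per-pair group label."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_a": [a for a, _ in self.pairs],
             "sample_b": [b for _, b in self.pairs],
             "group": self.groups}
        )


_NEEDED = {"patient_id": "patient_relation", "ward": "ward_relation"}


def _pair_ok(ra, rb, c: PairConstraints) -> bool:
    if c.patient_relation == "different" and ra.patient_id == rb.patient_id:
        return False
    if c.patient_relation == "same" and ra.patient_id != rb.patient_id:
        return False
    wr = c.ward_relation
    if wr == "same" and ra.ward != rb.ward:
        return False
    if wr == "different" and ra.ward == rb.ward:
        return False
    if isinstance(wr, tuple) and {ra.ward, rb.ward} != set(wr):
        return False
    tm = c.time_matching
    if tm == "same_calendar_week" and ra.calendar_week != rb.calendar_week:
        return False
    if tm == "same_day_of_life" and ra.day_of_life != rb.day_of_life:
        return False
    if isinstance(tm, tuple) and {ra.day_of_life, rb.day_of_life} != {tm[1], tm[2]}:
        return False
    return True


def _group_label(ra, rb, c: PairConstraints) -> str:
    parts = []
    if c.time_matching == "same_calendar_week":
        parts.append(f"week={ra.calendar_week}")
    elif c.time_matching == "same_day_of_life":
        parts.append(f"day={ra.day_of_life}")
    elif isinstance(c.time_matching, tuple):
        parts.append(f"days={c.time_matching[1]}-{c.time_matching[2]}")
    if c.ward_relation == "same":
        parts.append(f"ward={ra.ward}")
    elif c.ward_relation == "different" or isinstance(c.ward_relation, tuple):
        parts.append("wards=" + "|".join(sorted({ra.ward, rb.ward})))
    return ";".join(parts) if parts else "all"


def select_pairs(meta: pd.DataFrame, constraints: PairConstraints) -> PairSet:
    """All unordered sample pairs satisfying the constraints.

    Output order is deterministic (lexicographic by sample ids) and
    invariant to metadata row order.
    """
    for col in ("patient_id", "ward", "calendar_week", "day_of_life"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks column {col!r} referenced by constraints")
    if isinstance(constraints.ward_relation, tuple):
        known = set(meta["ward"])
        missing = set(constraints.ward_relation) - known
        if missing:
            raise ValueError(f"ward(s) not present in metadata: {sorted(missing)}")

    meta = meta.sort_index()
    rows = {sid: row for sid, row in meta.iterrows()}
    out = PairSet()
    for a, b in combinations(sorted(rows), 2):
        if _pair_ok(rows[a], rows[b], constraints):
            out.pairs.append((a, b))
            out.groups.append(_group_label(rows[a], rows[b], constraints))
    return out


def founder_pairs(
    meta: pd.DataFrame,
    founder_day: int,
    later_days: list[int],
) -> PairSet:
    """Cross-patient pairs of a founder-timepoint sample with later samples.

    Pairs one sample taken at ``founder_day`` (day of life) with one
    sample taken at each day in ``later_days``, always between different
    patients, grouped by ``(founder_day, later_day)``. ``later_days`` may
    include ``founder_day`` itself (e.g. the day-3 versus day-3
    comparison).
    """
    founders = meta[meta["day_of_life"] == founder_day]
    if founders.empty:
        raise ValueError(f"no samples at founder day {founder_day}")
    out = PairSet()
    seen = set()
    for later in later_days:
        laters = meta[meta["day_of_life"] == later]
        for fa in sorted(founders.index):
            for lb in sorted(laters.index):
                if fa == lb:
                    continue
                if founders.loc[fa, "patient_id"] == laters.loc[lb, "patient_id"]:
                    continue
                key = tuple(sorted((fa, lb)))
                if key in seen:
                    continue
                seen.add(key)
                out.pairs.append(key)
                out.groups.append(f"days={founder_day}-{later}")
    return out
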