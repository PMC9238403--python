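"""Core data containers: community tables, sample metadata, input alignment.

The universal currency of the pipeline is the :class:`CommunityTable`, a
samples x taxa nonnegative abundance matrix. Phylogenies are scikit-bio
``TreeNode`` objects (rooted, branch lengths required) and patristic
distances live in ``skbio.DistanceMatrix``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CommunityTable",
    "AlignmentReport",
    "METADATA_REQUIRED_COLUMNS",
    "validate_metadata",
    "align_inputs",
]

#: Columns every sample-metadata table must carry. Additional numeric
#: columns are treated as covariates (e.g. CRP, weight, FiO2).
METADATA_REQUIRED_COLUMNS = (
    "sample_id",
    "patient_id",
    "ward",
    "day_of_life",
    "calendar_week",
    "postconception_days",
)


@dataclass
class CommunityTable:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are taxa; values nonnegative. Integer
        counts before any absolute-abundance scaling.
    is_absolute : bool
        True once abundances have been scaled to absolute loads
        (copies per gram); False for raw/rarefied counts.
    """

    data: pd.DataFrame
    is_absolute: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        values = self.data.to_numpy()
        if values.size and np.nanmin(values) < 0:
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[r]!r}, "
                f"taxon {self.data.columns[c]!r}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def abundance(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def sample_vector(self, sample_id: str) -> np.ndarray:
        """Abundance vector of one sample, ordered by ``taxon_ids``."""
        return self.data.loc[sample_id].to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "CommunityTable":
        return replace(self, data=self.data.loc[list(sample_ids)])

    def subset_taxa(self, taxon_ids) -> "CommunityTable":
        return replace(self, data=self.data[list(taxon_ids)])


@dataclass
class AlignmentReport:
    """Ids dropped while aligning table, tree and metadata."""

    dropped_taxa_not_in_tree: list[str] = field(default_factory=list)
    dropped_tips_not_in_table: list[str] = field(default_factory=list)
    dropped_samples_without_metadata: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"dropped {len(self.dropped_taxa_not_in_tree)} taxa absent from tree, "
            f"{len(self.dropped_tips_not_in_table)} tree tips absent from table, "
            f"{len(self.dropped_samples_without_metadata)} samples without metadata"
        )


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and invariants of a sample-metadata table.

    Returns a copy indexed by ``sample_id``. Any numeric column beyond the
    required set is available as a covariate for the driver regression.
    """
    missing = [c for c in METADATA_REQUIRED_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dups}")
    if (meta["day_of_life"] < 0).any():
        raise ValueError("day_of_life must be >= 0")
    out = meta.copy()
    out.index = pd.Index(out["sample_id"], name="sample_id")
    return out


def _check_tree(tree: TreeNode) -> None:
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("tree has duplicate tip labels")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("tree has missing branch lengths; patristic distances undefined")
        if node.length < 0:
            raise ValueError("tree has negative branch lengths")


def align_inputs(
    table: CommunityTable,
    tree: TreeNode,
    meta: pd.DataFrame,
) -> tuple[CommunityTable, TreeNode, pd.DataFrame, AlignmentReport]:
    """Restrict table, tree and metadata to their common samples and taxa.

    Taxa are restricted to the intersection of table columns and tree tips
    (tree pruned accordingly); samples to those with a metadata row. The
    operation is idempotent: aligning an aligned triple is a no-op.

    Raises
    ------
    ValueError
        If the taxon intersection is empty.
    """
    _check_tree(tree)
    if "sample_id" in meta.columns and meta.index.name != "sample_id":
        meta = validate_metadata(meta)

    tip_names = {t.name for t in tree.tips()}
    table_taxa = set(table.taxon_ids)
    shared = table_taxa & tip_names
    if not shared:
        raise ValueError("no taxa shared between count table and tree tips")

    report = AlignmentReport(
        dropped_taxa_not_in_tree=sorted(table_taxa - shared),
        dropped_tips_not_in_table=sorted(tip_names - shared),
    )

    kept_taxa = [t for t in table.taxon_ids if t in shared]
    out_table = table.subset_taxa(kept_taxa)

    out_tree = tree.shear(sorted(shared)) if tip_names - shared else tree

    with_meta = [s for s in out_table.sample_ids if s in meta.index]
    report.dropped_samples_without_metadata = sorted(
        set(out_table.sample_ids) - set(with_meta)
    )
    out_table = out_table.subset_samples(with_meta)
    out_meta = meta.loc[with_meta]
    return out_table, out_tree, out_meta, report
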