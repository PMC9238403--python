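"""Readers and writers for the pipeline's delimited-text interfaces.

Count tables are TSV/CSV with a header row of ids and the first column
holding the other axis' ids; trees are newick with branch lengths;
metadata, loads and copy numbers are TSV with documented column names.
All outputs are written as TSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CommunityTable, validate_metadata

__all__ = [
    "read_count_table",
    "read_tree",
    "read_metadata",
    "read_loads",
    "read_copy_numbers",
    "write_count_table",
]


def _sep_for(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_count_table(path, orientation: str = "samples_as_rows") -> CommunityTable:
    """Read a delimited count table into a :class:`CommunityTable`.

    Parameters
    ----------
    path : str or Path
        TSV (default) or CSV file; first column holds row ids.
    orientation : {"samples_as_rows", "taxa_as_rows"}
        Declared layout of the file; ``taxa_as_rows`` is transposed so the
        returned table is always samples x taxa.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ValueError(
                f"non-numeric cell in column {col!r}, row(s) {list(bad)[:3]}"
            )
    values = df.to_numpy()
    if values.size and values.min() < 0:
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if orientation == "taxa_as_rows":
        df = df.T
    return CommunityTable(data=df, is_absolute=False)


def write_count_table(table: CommunityTable, path) -> None:
    table.data.to_csv(path, sep=_sep_for(path))


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; branch lengths are required.

    Raises
    ------
    ValueError
        On missing branch lengths (patristic distances would be
        undefined), duplicate tips, or fewer than two tips.
    """
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 tips")
    if len(tips) != len(set(tips)):
        raise ValueError("tree has duplicate tip labels")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(f"missing branch length at node {node.name!r}")
    return tree


def read_metadata(path) -> pd.DataFrame:
    """Read the sample-metadata TSV and validate required columns."""
    meta = pd.read_csv(path, sep=_sep_for(path))
    return validate_metadata(meta)


def read_loads(path) -> dict[str, float]:
    """Per-sample total 16S load TSV with columns ``sample_id``, ``load``."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if not {"sample_id", "load"} <= set(df.columns):
        raise ValueError("loads file needs columns: sample_id, load")
    return dict(zip(df["sample_id"].astype(str), df["load"].astype(float)))


def read_copy_numbers(path) -> dict[str, float]:
    """Per-taxon 16S copy-number TSV with columns ``taxon_id``, ``copy_number``."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if not {"taxon_id", "copy_number"} <= set(df.columns):
        raise ValueError("copy-number file needs columns: taxon_id, copy_number")
    return dict(zip(df["taxon_id"].astype(str), df["copy_number"].astype(float)))
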