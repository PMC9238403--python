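import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from ecoassembly.containers import CommunityTable


@pytest.fixture
def three_taxon_tree() -> TreeNode:
    """((A:1,B:1):1,C:2); — the hand-computable toy phylogeny."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def toy_table() -> CommunityTable:
    """5 samples x 6 taxa integer count table used by preprocessing tests."""
    data = pd.DataFrame(
        [
            [10, 0, 5, 0, 1, 0],
            [8, 2, 0, 0, 1, 0],
            [0, 3, 0, 0, 2, 0],
            [4, 0, 0, 6, 0, 0],
            [1, 1, 1, 1, 1, 0],
        ],
        index=[f"S{i}" for i in range(1, 6)],
        columns=[f"t{i}" for i in range(1, 7)],
    )
    return CommunityTable(data=data)


@pytest.fixture
def toy_meta() -> pd.DataFrame:
    """Metadata for three patients across two wards and two weeks."""
    meta = pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3", "S4", "S5"],
            "patient_id": ["P1", "P1", "P2", "P2", "P3"],
            "ward": ["NICU-1", "NICU-1", "NICU-1", "IMCU-1", "NICU-1"],
            "day_of_life": [3, 10, 3, 10, 3],
            "calendar_week": [1, 2, 1, 2, 1],
            "postconception_days": [170, 177, 182, 189, 175],
        }
    )
    meta.index = pd.Index(meta["sample_id"], name="sample_id")
    return meta


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
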