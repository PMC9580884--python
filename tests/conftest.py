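import io

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from divcom import AbundanceTable


def euclidean_dm(points, ids=None) -> DistanceMatrix:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    if ids is None:
        ids = [f"P{i:02d}" for i in range(points.shape[0])]
    return DistanceMatrix(squareform(pdist(points)), ids=list(ids))


@pytest.fixture
def make_euclidean():
    return euclidean_dm


@pytest.fixture
def caterpillar_tree() -> TreeNode:
    """3-leaf tree ((A:1,B:1):1,C:2) used throughout the distance tests."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def small_table() -> AbundanceTable:
    return AbundanceTable(
        pd.DataFrame(
            {"S1": [5.0, 0.0], "S2": [0.0, 3.0], "S3": [2.0, 1.0]},
            index=["OTU_1", "OTU_2"],
        )
    )
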