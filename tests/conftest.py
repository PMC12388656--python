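import numpy as np
import pandas as pd
import pytest

from assemblyscape import CommunityTable, read_tree


@pytest.fixture
def toy_tree():
    """Three-tip caterpillar: ((A:1,B:1):1,C:2); — d(A,B)=2, d(A,C)=4."""
    return read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        [[5, 1, 1, 2], [0, 3, 3, 0], [2, 2, 2, 2]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C", "D"],
    )
    metadata = pd.DataFrame(
        {"site": ["x", "y", "z"], "layer": ["T", "M", "S"],
         "grassland": ["AM", "TG", "DG"]},
        index=counts.index,
    )
    return CommunityTable(counts, metadata)


def make_table(counts: np.ndarray, taxa=None, samples=None,
               layer="T") -> CommunityTable:
    counts = np.asarray(counts)
    samples = samples or [f"s{i}" for i in range(counts.shape[0])]
    taxa = taxa or [f"t{j}" for j in range(counts.shape[1])]
    metadata = pd.DataFrame(
        {"site": samples, "layer": layer, "grassland": "AM"}, index=samples)
    return CommunityTable(
        pd.DataFrame(counts, index=samples, columns=taxa), metadata)
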