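import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from continuum_assembly.datamodel import CommunityTable


@pytest.fixture
def small_table():
    """5 taxa x 6 samples with assorted sharing structure."""
    rng = np.random.default_rng(11)
    data = rng.integers(0, 20, size=(6, 5))
    data[0, :] += 1  # no empty samples
    data[:, 0] += 1
    return CommunityTable(pd.DataFrame(
        data, index=[f"s{i}" for i in range(6)],
        columns=[f"t{i}" for i in range(5)]))


@pytest.fixture
def cherry_tree():
    return TreeNode.read(io.StringIO("(A:1,B:2):0;"))


@pytest.fixture
def three_tip_tree():
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2):0;"))


def balanced_newick(n_tips: int, length: float = 1.0) -> str:
    """Perfectly balanced binary tree with n_tips a power of two."""
    labels = [f"L{i}" for i in range(n_tips)]

    def build(lo, hi):
        if hi - lo == 1:
            return f"{labels[lo]}:{length}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{length}"

    return build(0, n_tips) + ";"


def caterpillar_newick(n_tips: int, length: float = 1.0) -> str:
    out = f"(C1:{length},C2:{length}):{length}"
    for i in range(3, n_tips + 1):
        out = f"({out},C{i}:{length}):{length}"
    return out + ";"
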