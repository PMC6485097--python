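import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from morphpars import CharacterMatrix, PhyloTree


@pytest.fixture
def small_matrix():
    """6 taxa x 5 characters with known brute-force statistics.

    Expected values (frozen from exhaustive enumeration over all 105
    topologies and every ancestral assignment): a single most-parsimonious
    tree of length 8 with per-character steps [1, 2, 1, 2, 2],
    m = [1, 1, 1, 1, 2], g = [2, 3, 2, 2, 3], hence CI = 6/8 = 0.75 and
    RI = (12 - 8) / (12 - 6) = 2/3.
    """
    rows = {
        "A": [0, 0, 0, 0, 2],
        "B": [0, 1, 0, (0, 1), 2],
        "C": [1, 0, 0, 1, 1],
        "D": [1, 1, 1, 1, 0],
        "E": [1, 0, 1, 0, 0],
        "F": [1, 1, None, 0, 0],
    }
    return CharacterMatrix.from_values(list(rows), list(rows.values()))


@pytest.fixture
def quartet_tree():
    """((A,B),(C,D)) as an unrooted tree."""
    taxa = ["A", "B", "C", "D"]
    adj = {0: [4], 1: [4], 2: [5], 3: [5], 4: [0, 1, 5], 5: [2, 3, 4]}
    return PhyloTree(adj, taxa)


def make_matrix(rows_dict, **kw):
    return CharacterMatrix.from_values(list(rows_dict), list(rows_dict.values()), **kw)
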