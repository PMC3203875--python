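import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from phylofoot import (
    AlignedSite,
    Alignment,
    ScoringMatrix,
    SiteMatch,
    parse_newick,
)

JASPAR_TEXT = """>MA0001.1 SOX2
A [ 10  0  1  0  8  0 ]
C [  0  9  0  0  1  0 ]
G [  0  1  0 10  1 10 ]
T [  0  0  9  0  0  0 ]
>MA0002.1 GATA1
A [ 0 12  0  0 ]
C [ 0  0  0 12 ]
G [12  0  0  0 ]
T [ 0  0 12  0 ]
"""

TRANSFAC_TEXT = """AC  M00001
XX
ID  V$SOX17
XX
P0      A      C      G      T
01      8      0      0      0      A
02      0      7      1      0      C
03      0      0      0      8      T
04      8      0      0      0      A
05      0      0      8      0      G
06      1      7      0      0      C
07      8      0      0      0      A
08      0      0      8      0      G
XX
//
"""


@pytest.fixture
def jaspar_text():
    return JASPAR_TEXT


@pytest.fixture
def transfac_text():
    return TRANSFAC_TEXT


@pytest.fixture
def cherry_tree():
    return parse_newick("((A:0.1,B:0.2):0.3,C:0.4);")


@pytest.fixture
def quartet_tree():
    return parse_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.15);")


def make_matrix(consensus, name="TF", matrix_id="MX1", weight=10.0,
                taxon_group=None):
    counts = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = weight
    return ScoringMatrix(matrix_id=matrix_id, tf_name=name, source="user",
                         counts=counts, taxon_group=taxon_group)


def make_site(species, name, s, e, l, seq_start=None, mss=0.9, strand="+",
              matrix_id="MX"):
    seq_start = seq_start if seq_start is not None else s
    match = SiteMatch(
        species=species, matrix_id=matrix_id, tf_name=name,
        seq_start=seq_start, seq_end=seq_start + l - 1, strand=strand,
        raw_score=1.0, mss=mss,
    )
    return AlignedSite(match=match, s=s, e=e, l=l)


@pytest.fixture
def site_factory():
    return make_site


@pytest.fixture
def matrix_factory():
    return make_matrix
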