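import numpy as np
import pytest

from lifecon.core_io import MotifModel, PhyloTree


@pytest.fixture
def three_taxon_tree() -> PhyloTree:
    """((A:1,B:1):1,C:2); — shared-branch covariance [[2,1,0],[1,2,0],[0,0,2]]."""
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_taxon_tree() -> PhyloTree:
    return PhyloTree.from_newick("(((A:1,B:2):0.5,C:1.5):1,D:3);")


@pytest.fixture
def width1_A_motif() -> MotifModel:
    """P(A)=1 single-column motif over a uniform background (2-bit score)."""
    return MotifModel("W1A", np.array([[1.0], [0.0], [0.0], [0.0]]), np.full(4, 0.25))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
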