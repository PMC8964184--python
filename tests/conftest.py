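import numpy as np
import pytest

from sfs2d import GenotypeMatrix, JointSFS, PopMap
from sfs2d.containers import DEPTH_UNKNOWN


def make_matrix(genotypes, depths=None, individuals=None, loci=None,
                pos=None):
    """Build a small GenotypeMatrix from a nested list of dosages."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind = genotypes.shape
    if depths is None:
        depths = np.full_like(genotypes, 30, dtype=np.int32)
    if individuals is None:
        individuals = [f"ind{i}" for i in range(n_ind)]
    if loci is None:
        loci = [f"loc{i}" for i in range(n_sites)]
    if pos is None:
        pos = list(range(1, n_sites + 1))
    return GenotypeMatrix(np.array(loci, dtype=object),
                          np.array(pos, dtype=np.int64),
                          np.array(["A"] * n_sites, dtype=object),
                          np.array(["T"] * n_sites, dtype=object),
                          genotypes,
                          np.asarray(depths, dtype=np.int32),
                          list(individuals))


@pytest.fixture
def two_pop_map():
    return PopMap({"ind0": "pop1", "ind1": "pop1", "ind2": "pop2",
                   "ind3": "pop2"})


@pytest.fixture
def small_matrix():
    # 4 individuals (2 per population), 5 sites on 3 loci
    return make_matrix(
        [[0, 1, 2, 0],
         [1, 1, 0, 0],
         [2, 2, 2, 2],
         [0, 0, 1, 2],
         [1, 0, 0, 1]],
        loci=["locA", "locA", "locB", "locB", "locC"],
        pos=[10, 40, 5, 9, 3],
    )


def random_jsfs(rng, n1, n2, folded=False):
    counts = rng.random((n1 + 1, n2 + 1)) * 10
    sfs = JointSFS(counts, folded=False)
    return sfs.fold() if folded else sfs
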