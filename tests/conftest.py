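import numpy as np
import pytest

from ercov import BranchRateVector, Phylogeny
from ercov.simulate import default_tree, random_topology


@pytest.fixture(scope="session")
def tree12():
    """The fixed 12-taxon simulation tree."""
    return default_tree()


@pytest.fixture
def tree4():
    return Phylogeny.from_newick("(A:0.1,B:0.2,(C:0.3,D:0.4):0.05);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_vector(tree, lengths, gene_id="g", species=None):
    """BranchRateVector on (a pruning of) `tree` from a branch-id->length
    mapping or an array in canonical branch order."""
    sub = tree if species is None else tree.prune(species)[0]
    if isinstance(lengths, dict):
        arr = np.array([lengths[b] for b in sub.branch_ids])
    else:
        arr = np.asarray(lengths, dtype=float)
    return BranchRateVector(
        gene_id=gene_id,
        species_set=sub.leaf_names,
        branch_ids=sub.branch_ids,
        lengths=arr,
    )
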