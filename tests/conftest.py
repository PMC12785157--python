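import numpy as np
import pytest

from paleochron.supermatrix import GeneAlignment, concatenate
from paleochron.trees import TimeTree


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


@pytest.fixture
def toy_genes():
    """Two small codon genes over three taxa (taxon C missing from gene2)."""
    g1 = GeneAlignment("gene1", ["A", "B", "C"],
                       ["ATGAAA", "ATGAAG", "ATGAAT"])
    g2 = GeneAlignment("gene2", ["A", "B"],
                       ["GGGCCCTTT", "GGGCCATTA"])
    return [g1, g2]


@pytest.fixture
def toy_matrix(toy_genes):
    return concatenate(toy_genes, lineage_of={"A": "L1", "B": "L1",
                                              "C": "L2"})


@pytest.fixture
def quartet_tree():
    """Ultrametric 4-taxon tree: ((a,b),(c,d)) with ages 100/150/250 Ma."""
    return TimeTree.from_newick(
        "((a:100,b:100):150,(c:150,d:150):100);", force_ultrametric=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
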