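import numpy as np
import pytest

from owlscan.alignment import CodonAlignment
from owlscan.tree import parse_newick_labeled


@pytest.fixture(scope="session")
def small_tree():
    """8-taxon unrooted tree with one internal foreground branch."""
    return parse_newick_labeled("(((A,B)#1,(C,D)),(E,F),(G,H));")


@pytest.fixture(scope="session")
def quartet_tree():
    return parse_newick_labeled("((A:0.2,B:0.15)#1:0.1,C:0.3,D:0.25);")


def make_alignment(gene_id, taxa, codon_rows):
    """Build an alignment from per-taxon lists of codons."""
    return CodonAlignment(gene_id, tuple(taxa),
                          tuple("".join(row) for row in codon_rows))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
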