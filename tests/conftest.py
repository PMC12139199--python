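import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from riceshift.reconcile import SpeciesIndex
from riceshift.trees import parse_newick


@pytest.fixture(scope="session")
def four_taxon_species():
    """Fixed 4-taxon species tree used by the reconciliation oracle tests."""

    return parse_newick("(((A,B)ab,C)abc,D)root;", leaf_delimiter=None)


@pytest.fixture(scope="session")
def rice_species():
    """Rice-like species tree: indica and japonica clades with two genomes
    each, an aus sister lineage and a wild outgroup."""

    return parse_newick(
        "(((((ind1,ind2)indica,(jap1,jap2)japonica)sativa,aus1)crown,wild1)oryza,out)root;",
        leaf_delimiter=None,
    )


@pytest.fixture(scope="session")
def rice_index(rice_species):
    return SpeciesIndex(rice_species)
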