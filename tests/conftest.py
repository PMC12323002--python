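import pytest

from taxfun.taxonomy import TaxNode, TaxonomyTree


@pytest.fixture
def two_species_tree() -> TaxonomyTree:
    """root -> genus G -> species A, B."""
    return TaxonomyTree(
        {
            "root": TaxNode("root", "root", "root", None),
            "G": TaxNode("G", "genus G", "genus", "root"),
            "A": TaxNode("A", "species A", "species", "G"),
            "B": TaxNode("B", "species B", "species", "G"),
        }
    )


@pytest.fixture
def full_lineage_tree() -> TaxonomyTree:
    """Seven-rank lineages for four species in two genera, one shared family."""
    nodes = {
        "root": TaxNode("root", "root", "root", None),
        "p1": TaxNode("p1", "p1", "phylum", "root"),
        "c1": TaxNode("c1", "c1", "class", "p1"),
        "o1": TaxNode("o1", "o1", "order", "c1"),
        "f1": TaxNode("f1", "f1", "family", "o1"),
        "g1": TaxNode("g1", "g1", "genus", "f1"),
        "g2": TaxNode("g2", "g2", "genus", "f1"),
        "s1": TaxNode("s1", "s1", "species", "g1"),
        "s2": TaxNode("s2", "s2", "species", "g1"),
        "s3": TaxNode("s3", "s3", "species", "g2"),
        "s4": TaxNode("s4", "s4", "species", "g2"),
        "strain1": TaxNode("strain1", "s1 strain X", "no-rank", "s1"),
    }
    return TaxonomyTree(nodes)
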