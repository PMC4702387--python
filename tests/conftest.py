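import numpy as np
import pytest

from corebin.model import TaxNode
from corebin.taxonomy import TaxonomyTree


@pytest.fixture
def chain_tree() -> TaxonomyTree:
    """root -> A -> B (three-node chain)."""
    return TaxonomyTree(
        [
            TaxNode(1, 1, "root", "root"),
            TaxNode(2, 1, "class", "A"),
            TaxNode(3, 2, "genus", "B"),
        ]
    )


@pytest.fixture
def lineage_tree() -> TaxonomyTree:
    """Two species per genus under one family, mimicking real rank structure.

    root(1) -> class(2) -> order(3) -> family(4) -> genus(5) -> species 6, 7
                                               \\-> genus(8) -> species 9
    """
    return TaxonomyTree(
        [
            TaxNode(1, 1, "root", "root"),
            TaxNode(2, 1, "class", "Mollicutes"),
            TaxNode(3, 2, "order", "Mycoplasmatales"),
            TaxNode(4, 3, "family", "Mycoplasmataceae"),
            TaxNode(5, 4, "genus", "Mycoplasma"),
            TaxNode(6, 5, "species", "Mycoplasma fermentans"),
            TaxNode(7, 5, "species", "Mycoplasma gallisepticum"),
            TaxNode(8, 4, "genus", "Ureaplasma"),
            TaxNode(9, 8, "species", "Ureaplasma urealyticum"),
        ]
    )


def random_tree(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """Random rooted tree: node i hangs off a uniform earlier node."""
    nodes = [TaxNode(1, 1, "root", "root")]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        nodes.append(TaxNode(i, parent, "clade", f"n{i}"))
    return TaxonomyTree(nodes)


def brute_force_lca(tree: TaxonomyTree, taxids: list[int]) -> int:
    """Independent oracle: intersect full ancestor paths, take the deepest."""
    common = set(tree.ancestors(taxids[0]))
    for t in taxids[1:]:
        common &= set(tree.ancestors(t))
    return max(common, key=tree.depth)
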