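import numpy as np
import pytest

from plastonoise import Alignment


@pytest.fixture
def tiny_alignment():
    return Alignment.from_sequences(
        [("t1", "AACA"), ("t2", "AACA"), ("t3", "ACC-"), ("t4", "AGCN")]
    )


def random_alignment(rng, n_taxa, n_cols, alphabet="ACGT-N"):
    chars = np.array(list(alphabet))
    rows = ["".join(rng.choice(chars, size=n_cols)) for _ in range(n_taxa)]
    return Alignment.from_sequences((f"t{i}", row) for i, row in enumerate(rows))


def random_additive_tree(rng, n_leaves, min_len=0.05, max_len=1.0):
    """Random binary unrooted tree (newick) with strictly positive lengths.

    Built by sequential leaf attachment to a uniformly chosen existing edge,
    so all unrooted topologies are reachable.
    """
    import dendropy

    taxa = [f"t{i}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)

    def blen():
        return float(rng.uniform(min_len, max_len))

    # start from a 3-leaf star
    for lab in taxa[:3]:
        child = tree.seed_node.new_child(taxon=tns.get_taxon(lab))
        child.edge.length = blen()
    for lab in taxa[3:]:
        edges = [
            e for e in tree.preorder_edge_iter() if e.tail_node is not None
        ]
        edge = edges[int(rng.integers(0, len(edges)))]
        old_head, tail = edge.head_node, edge.tail_node
        new_internal = dendropy.Node()
        tail.remove_child(old_head)
        tail.add_child(new_internal)
        new_internal.edge.length = edge.length / 2
        new_internal.add_child(old_head)
        old_head.edge.length = edge.length / 2
        leaf = new_internal.new_child(taxon=tns.get_taxon(lab))
        leaf.edge.length = blen()
    tree.is_rooted = False
    return tree


def path_distance_matrix(tree):
    """Leaf-to-leaf path distances of a dendropy tree, as a DistanceMatrix."""
    from plastonoise import DistanceMatrix

    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(
        (lf.taxon for lf in tree.leaf_node_iter()), key=lambda t: t.label
    )
    n = len(taxa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pdm.distance(taxa[i], taxa[j])
    return DistanceMatrix(
        tuple(t.label for t in taxa), values, np.full((n, n), 1), "p_distance"
    )
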