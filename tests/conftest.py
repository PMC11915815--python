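import dendropy
import numpy as np
import pytest

from panpm import simulate as sim


@pytest.fixture(scope="session")
def default_spec():
    return sim.default_spec(seed=1)


@pytest.fixture(scope="session")
def bundle(default_spec):
    """The default synthetic pangenome used across modules."""
    return sim.generate_pangenome(default_spec)


def random_unrooted_tree(labels: list[str], rng: np.random.Generator) -> dendropy.Tree:
    """Uniform-ish random unrooted binary tree by sequential attachment."""
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False
    edges = []
    for lab in labels[:3]:
        leaf = dendropy.Node()
        leaf.taxon = tns.get_taxon(lab)
        leaf.edge.length = float(rng.uniform(0.05, 1.0))
        tree.seed_node.add_child(leaf)
        edges.append(leaf.edge)
    for lab in labels[3:]:
        e = edges[int(rng.integers(0, len(edges)))]
        head = e.head_node
        parent = head.parent_node
        mid = dendropy.Node()
        parent.remove_child(head)
        parent.add_child(mid)
        mid.add_child(head)
        length = e.length or 0.2
        mid.edge.length = length / 2
        head.edge.length = length / 2
        leaf = dendropy.Node()
        leaf.taxon = tns.get_taxon(lab)
        leaf.edge.length = float(rng.uniform(0.05, 1.0))
        mid.add_child(leaf)
        edges.extend([leaf.edge, head.edge, mid.edge])
    return tree


def brute_force_is_clan(tree: dendropy.Tree, target: set[str]) -> bool:
    """Edge-enumeration oracle for clan membership."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    target = frozenset(target)
    if target == all_leaves:
        return True
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if below == target or all_leaves - below == target:
            return True
    return False
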