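"""Distances, neighbor joining, clan queries, rooting, jackknife support,
and majority-rule consensus."""

import math

import dendropy
import dendropy.calculate.treecompare as treecompare
import numpy as np
import pytest

from panpm import phylo, simulate as sim
from panpm.phylo import ClanQuery
from panpm.seqprep import Alignment

from conftest import brute_force_is_clan, random_unrooted_tree


def _tree(newick: str, rooted: bool = False) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = rooted
    return t


# ---------------------------------------------------------------------------
# distances


def test_identical_rows_zero_distance():
    ids, D = phylo.poisson_distance(Alignment(["a", "b"], ["ACDEF", "ACDEF"]))
    assert D[0, 1] == 0.0


def test_half_mismatch_gives_ln2():
    ids, D = phylo.poisson_distance(Alignment(["a", "b"], ["AAAA", "AACC"]))
    assert D[0, 1] == pytest.approx(math.log(2))


def test_saturated_pair_capped():
    ids, D = phylo.poisson_distance(Alignment(["a", "b"], ["AAAA", "CCCC"]))
    assert D[0, 1] == 10.0


def test_zero_overlap_errors():
    with pytest.raises(ValueError, match="a.*b|b.*a"):
        phylo.poisson_distance(Alignment(["a", "b"], ["AA--", "--CC"]))


def test_gaps_excluded_pairwise():
    ids, D = phylo.poisson_distance(Alignment(["a", "b"], ["AC-D", "ACX D".replace(" ", "")]))
    assert D[0, 1] == 0.0  # the gap/X column is excluded; the rest match


# ---------------------------------------------------------------------------
# neighbor joining


def test_three_taxon_closed_form():
    ids = ["a", "b", "c"]
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    tree = phylo.neighbor_joining(ids, D)
    lengths = {
        leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
    }
    assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})


def test_additive_matrix_recovers_topology():
    rng = np.random.default_rng(17)
    for trial in range(20):
        n = int(rng.integers(5, 17))
        labels = [f"t{i}" for i in range(n)]
        true = random_unrooted_tree(labels, rng)
        tns = true.taxon_namespace
        pdm = true.phylogenetic_distance_matrix()
        D = np.array(
            [[pdm.distance(tns.get_taxon(a), tns.get_taxon(b)) for b in labels]
             for a in labels]
        )
        est = phylo.neighbor_joining(labels, D)
        est2 = dendropy.Tree.get(
            data=est.as_string(schema="newick"), schema="newick", taxon_namespace=tns
        )
        true.encode_bipartitions()
        est2.encode_bipartitions()
        assert treecompare.symmetric_difference(true, est2) == 0


def test_taxon_order_permutation_invariance():
    rng = np.random.default_rng(23)
    labels = [f"t{i}" for i in range(8)]
    true = random_unrooted_tree(labels, rng)
    tns = true.taxon_namespace
    pdm = true.phylogenetic_distance_matrix()
    D = np.array(
        [[pdm.distance(tns.get_taxon(a), tns.get_taxon(b)) for b in labels]
         for a in labels]
    )
    perm = list(rng.permutation(len(labels)))
    t1 = phylo.neighbor_joining(labels, D)
    t2 = phylo.neighbor_joining([labels[i] for i in perm], D[np.ix_(perm, perm)])
    shared = dendropy.TaxonNamespace(labels)
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                          taxon_namespace=shared)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                          taxon_namespace=shared)
    a.encode_bipartitions()
    b.encode_bipartitions()
    assert treecompare.symmetric_difference(a, b) == 0


def test_asymmetric_matrix_errors():
    D = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
    with pytest.raises(ValueError, match="symmetric"):
        phylo.neighbor_joining(["a", "b", "c"], D)


# ---------------------------------------------------------------------------
# clans


def test_clan_examples():
    t = _tree("((a,b),(c,d),e);")
    assert phylo.is_clan(t, {"a", "b"})
    assert not phylo.is_clan(t, {"a", "c"})
    assert phylo.is_clan(t, {"c", "d", "e"})  # complement side of {a,b}
    assert phylo.is_clan(t, {"a", "b", "c", "d", "e"})


def test_unknown_leaf_errors():
    with pytest.raises(ValueError, match="unknown"):
        phylo.is_clan(_tree("((a,b),(c,d),e);"), {"a", "z"})


def test_clan_matches_brute_force_enumeration():
    rng = np.random.default_rng(41)
    for trial in range(200):
        n = int(rng.integers(4, 13))
        labels = [f"x{i}" for i in range(n)]
        t = random_unrooted_tree(labels, rng)
        k = int(rng.integers(1, n + 1))
        sub = set(rng.choice(labels, size=k, replace=False))
        assert phylo.is_clan(t, sub) == brute_force_is_clan(t, sub)


def test_rooted_tree_requires_monophyly():
    t = _tree("((a,b),(c,d));", rooted=True)
    assert phylo.is_clan(t, {"a", "b"})
    assert not phylo.is_clan(t, {"a", "c"})
    # the complement of a clade is not a clade on a rooted tree
    assert not phylo.is_clan(t, {"c", "d", "a"})


def test_root_on_clan_outgroup_subtree():
    t = _tree("((a:1,b:1):1,(c:1,d:1):1,e:1);")
    rooted = phylo.root_on_clan(t, {"a", "b"})
    assert rooted.is_rooted
    kids = [
        sorted(l.taxon.label for l in child.leaf_iter())
        for child in rooted.seed_node.child_nodes()
    ]
    assert ["a", "b"] in kids


def test_root_on_non_clan_errors():
    t = _tree("((a,b),(c,d),e);")
    with pytest.raises(ValueError, match="not a clan"):
        phylo.root_on_clan(t, {"a", "c"})


def test_rooting_survives_newick_round_trip(tmp_path):
    t = _tree("((a:1,b:1):1,(c:1,d:1):1,e:1);")
    rooted = phylo.root_on_clan(t, {"a", "b"})
    path = tmp_path / "t.nwk"
    phylo.write_newick(rooted, path)
    back = phylo.read_newick(path)
    assert back.is_rooted
    kids = [
        sorted(l.taxon.label for l in child.leaf_iter())
        for child in back.seed_node.child_nodes()
    ]
    assert ["a", "b"] in kids


def test_newick_round_trip_preserves_metadata_labels(tmp_path):
    tree = sim.simulate_scenario_tree("E", 2, 0.25, 3)
    path = tmp_path / "e.nwk"
    phylo.write_newick(tree, path)
    back = phylo.read_newick(path)
    assert phylo.leaf_labels(back) == phylo.leaf_labels(tree)
    lengths_a = sorted(
        round(l.edge.length, 6) for l in tree.leaf_node_iter()
    )
    lengths_b = sorted(round(l.edge.length, 6) for l in back.leaf_node_iter())
    assert lengths_a == lengths_b


# ---------------------------------------------------------------------------
# jackknife


@pytest.fixture(scope="module")
def scenario_family():
    tree = sim.simulate_scenario_tree("E", 8, 0.0, 3)
    leaves = sorted(phylo.leaf_labels(tree))
    root = sim._random_protein(np.random.default_rng(1), 300)
    seqs = sim.evolve_protein(tree, root, 1.0, seed=7)
    ali = Alignment(leaves, [seqs[l] for l in leaves])
    members: dict[str, list[str]] = {}
    for l in leaves:
        members.setdefault(sim.parse_leaf_label(l)[2], []).append(l)
    return members, ali


def test_query_selecting_all_leaves_has_full_support(scenario_family):
    members, ali = scenario_family
    q = ClanQuery("all", frozenset(members))
    table, _ = phylo.jackknife_clan_support(members, ali, [q], 5, 10, seed=2)
    assert table.proportion("all") == 1.0


def test_jackknife_deterministic_under_seed(scenario_family):
    members, ali = scenario_family
    q = ClanQuery("ab", frozenset({"Mur_alpha", "Mur_beta"}))
    t1, _ = phylo.jackknife_clan_support(members, ali, [q], 5, 20, seed=5)
    t2, _ = phylo.jackknife_clan_support(members, ali, [q], 5, 20, seed=5)
    assert t1.rows == t2.rows


def test_clan_and_complement_have_equal_support(scenario_family):
    members, ali = scenario_family
    target = {"Mur_alpha", "Mur_beta"}
    complement = set(members) - target
    qs = [
        ClanQuery("clan", frozenset(target)),
        ClanQuery("complement", frozenset(complement)),
    ]
    table, _ = phylo.jackknife_clan_support(members, ali, qs, 5, 20, seed=6)
    assert table.proportion("clan") == table.proportion("complement")


def test_empty_member_errors(scenario_family):
    members, ali = scenario_family
    bad = dict(members) | {"ghost": []}
    with pytest.raises(ValueError, match="ghost"):
        phylo.jackknife_clan_support(bad, ali, [], 5, 5, seed=0)


# ---------------------------------------------------------------------------
# consensus


def test_consensus_of_identical_trees():
    tns = dendropy.TaxonNamespace()
    t = dendropy.Tree.get(data="((a,b),(c,d),e);", schema="newick", taxon_namespace=tns)
    t.is_rooted = False
    cons = phylo.majority_consensus([t] * 10)
    for leafset in ({"a", "b"}, {"c", "d"}):
        assert phylo.is_clan(cons, leafset)
    supports = [
        float(n.label) for n in cons.preorder_node_iter() if n.label is not None
    ]
    assert supports and all(s == 1.0 for s in supports)


def test_consensus_majority_fraction():
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data="((a,b),(c,d),e);", schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data="((a,c),(b,d),e);", schema="newick", taxon_namespace=tns)
    t1.is_rooted = t2.is_rooted = False
    cons = phylo.majority_consensus([t1] * 6 + [t2] * 4)
    assert phylo.is_clan(cons, {"a", "b"})
    assert "0.6000" in {n.label for n in cons.preorder_node_iter() if n.label}


def test_consensus_disjoint_leaf_sets_errors():
    t1 = _tree("((a,b),(c,d),e);")
    t2 = _tree("((p,q),(r,s),t);")
    with pytest.raises(ValueError):
        phylo.majority_consensus([t1, t2])


def test_consensus_empty_list_errors():
    with pytest.raises(ValueError):
        phylo.majority_consensus([])
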