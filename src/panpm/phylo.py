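"""Desk-scale tree inference and clan analytics.

Trees are dendropy objects whose leaf labels may carry metadata encoded
as ``id|taxon|member|domain``.  The module provides Poisson-corrected
protein distances, a deterministic neighbor-joining builder, clan
queries (a clan is a leaf set separable from the rest by removing one
edge — the unrooted analog of monophyly), rooting on a clan, jackknife
species-resampling with clan-support proportions, and a majority-rule
bipartition consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import dendropy
import numpy as np

from .seqprep import AA_ORDER, Alignment, mask_sites

_DIST_CAP = 10.0


@dataclass(frozen=True)
class ClanQuery:
    """Select leaves by member annotation; name used in support tables."""

    name: str
    members: frozenset[str]


@dataclass
class SupportTable:
    """query name -> (evaluable replicates, supporting replicates, proportion)."""

    rows: dict[str, tuple[int, int, float]] = field(default_factory=dict)

    def proportion(self, name: str) -> float:
        return self.rows[name][2]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("query\tn_evaluable\tn_supporting\tproportion\n")
            for name in sorted(self.rows):
                n_eval, n_sup, prop = self.rows[name]
                fh.write(f"{name}\t{n_eval}\t{n_sup}\t{prop:.4f}\n")


# ---------------------------------------------------------------------------
# newick io


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(
            schema="newick",
            suppress_rooting=False,
            real_value_format_specifier=".6f",
        )
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


# ---------------------------------------------------------------------------
# distances & neighbor joining


def poisson_distance(alignment: Alignment) -> tuple[list[str], np.ndarray]:
    """Poisson-corrected pairwise distances d = -ln(1 - p).

    p is the mismatch fraction over pairwise-comparable columns (gaps
    and ambiguous residues excluded per pair); distances are capped at
    10 for saturated pairs.  Errors on pairs with zero overlap.
    """
    if alignment.n_rows < 2:
        raise ValueError("need >= 2 sequences")
    arr = np.frombuffer(
        "".join(alignment.rows).encode(), dtype="S1"
    ).reshape(alignment.n_rows, alignment.n_cols)
    valid = np.isin(arr, np.frombuffer(AA_ORDER.encode(), dtype="S1"))
    n = alignment.n_rows
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            overlap = int(both.sum())
            if overlap == 0:
                raise ValueError(
                    f"zero pairwise overlap between {alignment.ids[i]!r} "
                    f"and {alignment.ids[j]!r}"
                )
            p = float((arr[i][both] != arr[j][both]).sum()) / overlap
            if p >= 1.0 - math.exp(-_DIST_CAP):
                d = _DIST_CAP
            else:
                d = -math.log(1.0 - p)
            D[i, j] = D[j, i] = d
    return list(alignment.ids), D


def neighbor_joining(ids: list[str], D: np.ndarray) -> dendropy.Tree:
    """Neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q criterion is chosen; ties break on the
    smallest (i, j) index pair in row-major order.  Negative estimated
    branch lengths are clamped to zero.  Returns an unrooted tree.
    """
    D = np.asarray(D, dtype=float)
    n = len(ids)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")

    tree = dendropy.Tree()
    tns = tree.taxon_namespace
    nodes: list[dendropy.Node] = []
    for label in ids:
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label=label)
        nodes.append(node)
    M = D.copy()

    while len(nodes) > 2:
        m = len(nodes)
        r = M.sum(axis=1)
        Q = (m - 2) * M - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major => smallest (i, j) on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = M[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = 0.5 * (M[i, :] + M[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        M2 = np.empty((m - 1, m - 1))
        M2[:-1, :-1] = M[np.ix_(keep, keep)]
        M2[-1, :-1] = dnew[keep]
        M2[:-1, -1] = dnew[keep]
        M2[-1, -1] = 0.0
        M = M2
        nodes = [nodes[k] for k in keep] + [parent]

    a, b = nodes
    b.edge.length = max(M[0, 1], 0.0)
    if a.is_leaf():
        a, b = b, a  # seed on an internal node where possible
        b.edge.length = max(M[0, 1], 0.0)
    a.add_child(b)
    tree.seed_node = a
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# clans


def _node_leafsets(tree: dendropy.Tree) -> list[tuple[dendropy.Node, frozenset[str]]]:
    below: dict[int, frozenset[str]] = {}
    out = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
        below[id(node)] = s
        out.append((node, s))
    return out


def is_clan(tree: dendropy.Tree, leafset: set[str]) -> bool:
    """True when one edge separates exactly ``leafset`` from the rest.

    On rooted trees this is monophyly; on unrooted trees the complement
    side counts as well.  The full leaf set is trivially a clan.
    """
    if not leafset:
        raise ValueError("leafset must be non-empty")
    target = frozenset(leafset)
    all_leaves = frozenset(leaf_labels(tree))
    unknown = target - all_leaves
    if unknown:
        raise ValueError(f"unknown leaves in query: {sorted(unknown)}")
    if target == all_leaves:
        return True
    for node, below in _node_leafsets(tree):
        if node is tree.seed_node:
            continue
        if below == target:
            return True
        if not tree.is_rooted and all_leaves - below == target:
            return True
    return False


def root_on_clan(tree: dendropy.Tree, leafset: set[str]) -> dendropy.Tree:
    """Root the tree on the edge separating ``leafset`` (the outgroup)
    from everything else, splitting that edge at its midpoint."""
    target = frozenset(leafset)
    all_leaves = frozenset(leaf_labels(tree))
    edge = None
    for node, below in _node_leafsets(tree):
        if node is tree.seed_node:
            continue
        if below == target or all_leaves - below == target:
            edge = node.edge
            break
    if edge is None:
        raise ValueError(
            f"leaf set {sorted(target)} is not separable by a single edge (not a clan)"
        )
    length = edge.length or 0.0
    tree.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# jackknife clan support


def nj_tree_builder(alignment: Alignment) -> dendropy.Tree:
    ids, D = poisson_distance(alignment)
    return neighbor_joining(ids, D)


def jackknife_clan_support(
    members: dict[str, list[str]],
    alignment: Alignment,
    queries: list[ClanQuery],
    k_per_member: int = 5,
    n_replicates: int = 100,
    seed: int = 0,
    tree_builder: Callable[[Alignment], dendropy.Tree] = nj_tree_builder,
    mask_min: float = 0.3,
    mask_max: float = 0.3,
) -> tuple[SupportTable, list[dendropy.Tree]]:
    """Clan support from random per-member sequence subsets.

    Each replicate samples min(k_per_member, member size) sequences per
    member without replacement, extracts their rows from the master
    alignment, masks poorly covered sites and sequences, and builds a
    tree.  A query's support is the fraction of replicates where its
    sampled leaves form a clan; replicates where a query selects fewer
    than two leaves present in the replicate tree are excluded from that
    query's denominator.
    """
    if k_per_member < 1:
        raise ValueError("k_per_member must be >= 1")
    empty = sorted(m for m, ids in members.items() if not ids)
    if empty:
        raise ValueError(f"members with no records: {empty}")
    member_of = {
        sid: member for member in members for sid in members[member]
    }
    rng = np.random.default_rng(seed)
    counts = {q.name: [0, 0] for q in queries}  # evaluable, supporting
    trees = []
    for _rep in range(n_replicates):
        sampled: list[str] = []
        for member in sorted(members):
            ids = sorted(members[member])
            k = min(k_per_member, len(ids))
            pick = rng.choice(len(ids), size=k, replace=False)
            sampled.extend(ids[i] for i in sorted(pick))
        sub = alignment.subset(sampled)
        sub = mask_sites(sub, mask_min, mask_max)
        tree = tree_builder(sub)
        trees.append(tree)
        present = leaf_labels(tree)
        for q in queries:
            sel = {sid for sid in present if member_of.get(sid) in q.members}
            if len(sel) < 2:
                continue
            counts[q.name][0] += 1
            if is_clan(tree, sel):
                counts[q.name][1] += 1
    table = SupportTable(
        {
            name: (n_eval, n_sup, n_sup / n_eval if n_eval else float("nan"))
            for name, (n_eval, n_sup) in counts.items()
        }
    )
    return table, trees


# ---------------------------------------------------------------------------
# consensus


def majority_consensus(trees: list[dendropy.Tree]) -> dendropy.Tree:
    """Majority-rule (> 50%) bipartition consensus.

    Trees are restricted to their shared leaf set first; each included
    internal edge carries its occurrence fraction as the node label.
    """
    if not trees:
        raise ValueError("empty tree list")
    leafsets = [leaf_labels(t) for t in trees]
    shared = frozenset.intersection(*(frozenset(s) for s in leafsets))
    if len(shared) < 3:
        raise ValueError("trees share fewer than 3 leaves")
    ref = min(shared)
    n = len(shared)
    counts: dict[frozenset[str], int] = {}
    for tree in trees:
        seen: set[frozenset[str]] = set()
        for node, below in _node_leafsets(tree):
            if node is tree.seed_node:
                continue
            side = frozenset(below & shared)
            if ref in side:
                side = shared - side
            if not 2 <= len(side) <= n - 2:
                continue
            seen.add(side)
        for side in seen:
            counts[side] = counts.get(side, 0) + 1
    total = len(trees)
    included = sorted(
        ((side, c / total) for side, c in counts.items() if c / total > 0.5),
        key=lambda sc: (-len(sc[0]), sorted(sc[0])),
    )

    tree = dendropy.Tree()
    tns = tree.taxon_namespace
    root = tree.seed_node
    node_leaves: dict[int, frozenset[str]] = {}
    for label in sorted(shared):
        leaf = dendropy.Node()
        leaf.taxon = tns.new_taxon(label=label)
        root.add_child(leaf)
        node_leaves[id(leaf)] = frozenset([label])
    node_leaves[id(root)] = frozenset(shared)

    for side, freq in included:
        # deepest current node containing the bipartition side
        host = root
        changed = True
        while changed:
            changed = False
            for child in host.child_nodes():
                if side <= node_leaves.get(id(child), frozenset()):
                    host = child
                    changed = True
                    break
        group = [c for c in host.child_nodes() if node_leaves[id(c)] <= side]
        new = dendropy.Node()
        new.label = f"{freq:.4f}"
        for c in group:
            host.remove_child(c)
            new.add_child(c)
        host.add_child(new)
        node_leaves[id(new)] = frozenset().union(*(node_leaves[id(c)] for c in group))
    tree.is_rooted = False
    return tree
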