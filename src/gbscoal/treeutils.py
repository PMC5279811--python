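"""Small shared helpers on :mod:`dendropy` trees.

All trees in this package are :class:`dendropy.Tree` objects whose leaves carry
taxa (``node.taxon.label``).  Unrooted comparisons suppress a degree-2 root, so
a rooted tree and its unrooted reading always agree on bipartitions and path
lengths.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "tree_from_newick",
    "leaf_labels",
    "path_edge_counts",
    "induced_quartet",
    "induced_triplet",
    "bipartition_set",
    "clade_set",
    "same_unrooted_topology",
    "same_rooted_topology",
    "collapse_short_branches",
    "strip_branch_lengths",
    "enumerate_unrooted_topologies",
    "enumerate_rooted_topologies",
    "rooted_nni_neighbors",
    "tree_from_groups",
]


def tree_from_newick(newick: str, rooted: bool = True) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True,
                             rooting="force-rooted" if rooted else "force-unrooted")
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _adjacency(tree: dendropy.Tree) -> dict:
    """Undirected adjacency with unit edge weights, degree-2 root suppressed."""
    adj: dict = {}

    def link(a, b):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            link(node, child)
    root = tree.seed_node
    if root in adj and len(adj[root]) == 2:
        a, b = adj.pop(root)
        adj[a] = [x for x in adj[a] if x is not root] + [b]
        adj[b] = [x for x in adj[b] if x is not root] + [a]
    return adj


def path_edge_counts(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Topological (edge-count) distances between all leaf pairs.

    Computed on the unrooted shape: a bifurcating root does not add an edge.
    The number of internal nodes *between* two leaves is ``D - 1``.
    """
    adj = _adjacency(tree)
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    index = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n), dtype=np.int64)
    for src in leaves:
        # BFS from each leaf
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj.get(u, ()):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        i = index[src]
        for lf, j in index.items():
            D[i, j] = dist[lf]
    return labels, D


def induced_quartet(D: np.ndarray, i: int, j: int, k: int, l: int):
    """Return the split an additive distance matrix induces on four tips.

    Result is a frozenset of two tip-index pairs, or ``None`` when the four
    tips are star-like (polytomy).
    """
    s_ij = D[i, j] + D[k, l]
    s_ik = D[i, k] + D[j, l]
    s_il = D[i, l] + D[j, k]
    m = min(s_ij, s_ik, s_il)
    winners = [s for s in (s_ij, s_ik, s_il) if s == m]
    if len(winners) > 1:
        return None
    if s_ij == m:
        return frozenset({frozenset({i, j}), frozenset({k, l})})
    if s_ik == m:
        return frozenset({frozenset({i, k}), frozenset({j, l})})
    return frozenset({frozenset({i, l}), frozenset({j, k})})


def induced_triplet(tree: dendropy.Tree, a: str, b: str, c: str):
    """Rooted triplet topology a rooted tree induces on three leaf labels.

    Returns the frozenset of the two cherry labels, or ``None`` if unresolved.
    """
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    nodes = [leaves[a], leaves[b], leaves[c]]
    depths = {}
    for lf in nodes:
        d = 0
        node = lf
        while node is not None:
            depths.setdefault(id(node), {})[lf.taxon.label] = d
            node = node.parent_node
            d += 1

    # walk up from a until a node is ancestral to all three
    node = leaves[a]
    while True:
        dd = depths.get(id(node), {})
        if all(lbl in dd for lbl in (a, b, c)):
            break
        node = node.parent_node
    top = node
    # pair whose mrca is strictly below `top`
    for x, y, z in ((a, b, c), (a, c, b), (b, c, a)):
        node = leaves[x]
        while True:
            dd = depths.get(id(node), {})
            if x in dd and y in dd:
                break
            node = node.parent_node
        if node is not top:
            return frozenset({x, y})
    return None


def bipartition_set(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions as frozensets-of-two-frozensets."""
    all_tips = frozenset(leaf_labels(tree))
    parts: set[frozenset] = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_tips - below
        if len(below) >= 2 and len(other) >= 2:
            parts.add(frozenset({below, other}))
    return parts


def clade_set(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial rooted clades (internal nodes below the root)."""
    all_tips = frozenset(leaf_labels(tree))
    clades: set[frozenset] = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(below) < len(all_tips):
            clades.add(below)
    return clades


def same_unrooted_topology(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    if set(leaf_labels(t1)) != set(leaf_labels(t2)):
        return False
    return bipartition_set(t1) == bipartition_set(t2)


def same_rooted_topology(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    if set(leaf_labels(t1)) != set(leaf_labels(t2)):
        return False
    return clade_set(t1) == clade_set(t2)


def collapse_short_branches(tree: dendropy.Tree, eps: float = 1e-8) -> dendropy.Tree:
    """Collapse internal edges shorter than ``eps`` into polytomies, in place."""
    to_collapse = [e for e in tree.preorder_edge_iter()
                   if e.head_node is not tree.seed_node
                   and not e.head_node.is_leaf()
                   and (e.length is None or e.length < eps)]
    for e in to_collapse:
        e.collapse()
    return tree


def strip_branch_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    for e in tree.preorder_edge_iter():
        e.length = None
    return tree


def _build(labels: Sequence[str], namespace: dendropy.TaxonNamespace,
           structure) -> dendropy.Tree:
    """Build a tree from a nested-tuple structure of labels."""
    tree = dendropy.Tree(taxon_namespace=namespace)

    def attach(parent, item):
        child = parent.new_child()
        if isinstance(item, tuple):
            for sub in item:
                attach(child, sub)
        else:
            child.taxon = namespace.require_taxon(label=item)

    if isinstance(structure, tuple):
        for item in structure:
            attach(tree.seed_node, item)
    else:
        tree.seed_node.taxon = namespace.require_taxon(label=structure)
    return tree


def enumerate_unrooted_topologies(labels: Sequence[str]) -> Iterator[dendropy.Tree]:
    """All unrooted binary topologies over ``labels`` (n>=3), as dendropy trees.

    Built by recursive leaf insertion into every edge; (2n-5)!! trees.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    namespace = dendropy.TaxonNamespace()

    # represent as nested tuples rooted at an internal trifurcation
    def insert(struct, leaf):
        # yield all structures with `leaf` inserted on every edge of struct
        if isinstance(struct, tuple):
            for idx, sub in enumerate(struct):
                for new_sub in insert(sub, leaf):
                    yield struct[:idx] + (new_sub,) + struct[idx + 1:]
        # attach on the edge above struct
        yield (struct, leaf)

    def gen(structs, remaining):
        if not remaining:
            yield from structs
            return
        leaf = remaining[0]
        nxt = []
        for s in structs:
            # insert into each of the three subtrees of the base trifurcation,
            # or next to the base as a new subtree is NOT valid (keeps degree 3)
            for idx in range(3):
                for new_sub in insert(s[idx], leaf):
                    nxt.append(s[:idx] + (new_sub,) + s[idx + 1:])
        yield from gen(nxt, remaining[1:])

    base = (labels[0], labels[1], labels[2])
    for struct in gen([base], labels[3:]):
        t = _build(labels, namespace, struct)
        t.is_rooted = False
        yield t


def enumerate_rooted_topologies(labels: Sequence[str]) -> Iterator[dendropy.Tree]:
    """All rooted binary topologies over ``labels`` (n>=2); (2n-3)!! trees."""
    labels = list(labels)
    namespace = dendropy.TaxonNamespace()

    def insert(struct, leaf):
        if isinstance(struct, tuple):
            for idx, sub in enumerate(struct):
                for new_sub in insert(sub, leaf):
                    yield struct[:idx] + (new_sub,) + struct[idx + 1:]
        yield (struct, leaf)

    def gen(structs, remaining):
        if not remaining:
            yield from structs
            return
        leaf = remaining[0]
        nxt = []
        for s in structs:
            nxt.extend(insert(s, leaf))
        yield from gen(nxt, remaining[1:])

    base = (labels[0], labels[1])
    for struct in gen([base], labels[2:]):
        t = _build(labels, namespace, struct)
        t.is_rooted = True
        yield t


def rooted_nni_neighbors(tree: dendropy.Tree) -> list[dendropy.Tree]:
    """Rooted nearest-neighbour-interchange neighbourhood of a binary tree.

    For each internal non-root node v with parent u, swapping one child of v
    with v's sibling yields two neighbours per internal edge.
    """
    newick = tree.as_string(schema="newick", suppress_rooting=True)
    neighbors = []
    base = tree_from_newick(newick, rooted=True)
    internal_edges = [e for e in base.preorder_edge_iter()
                      if e.head_node is not base.seed_node
                      and not e.head_node.is_leaf()]
    for eidx in range(len(internal_edges)):
        for which in (0, 1):
            t = tree_from_newick(newick, rooted=True)
            edges = [e for e in t.preorder_edge_iter()
                     if e.head_node is not t.seed_node
                     and not e.head_node.is_leaf()]
            v = edges[eidx].head_node
            u = v.parent_node
            siblings = [c for c in u.child_nodes() if c is not v]
            if len(siblings) != 1 or len(v.child_nodes()) != 2:
                continue
            s = siblings[0]
            c = v.child_nodes()[which]
            u.remove_child(s)
            v.remove_child(c)
            v.add_child(s)
            u.add_child(c)
            neighbors.append(t)
    return neighbors


def tree_from_groups(structure, namespace: dendropy.TaxonNamespace | None = None,
                     rooted: bool = True) -> dendropy.Tree:
    """Convenience: build a tree from nested tuples of labels, e.g. (('A','B'),'C')."""
    ns = namespace or dendropy.TaxonNamespace()
    t = _build([], ns, structure)
    t.is_rooted = rooted
    return t
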