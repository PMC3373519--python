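"""Lightweight unrooted binary trees for parsimony search.

Trees over ``n`` taxa are adjacency maps: leaves are ids ``0..n-1``,
internal (degree-3) nodes get larger ids.  Topologies are identified by
their set of non-trivial splits (each split stored as the frozenset of
leaf ids on the side not containing leaf 0), which doubles as a canonical
form for deduplication and consensus.  Newick conversion goes through
dendropy so annotated trees interoperate with standard tools.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Iterator

import dendropy
import numpy as np

Adj = dict[int, list[int]]

__all__ = [
    "copy_adj", "leaves", "edges", "splits", "random_tree", "all_topologies",
    "star_with_three", "insert_leaf_on_edge", "spr_neighbors", "tbr_neighbors",
    "nni_across_edge", "to_newick", "from_newick", "strict_consensus_splits",
]


def copy_adj(adj: Adj) -> Adj:
    return {k: list(v) for k, v in adj.items()}


def leaves(adj: Adj) -> list[int]:
    return sorted(k for k, v in adj.items() if len(v) == 1)


def edges(adj: Adj) -> list[tuple[int, int]]:
    return [(u, v) for u in adj for v in adj[u] if u < v]


def _component(adj: Adj, start: int, blocked: int) -> set[int]:
    """Nodes reachable from ``start`` without crossing the edge to ``blocked``."""
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if u == start and w == blocked:
                continue
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def splits(adj: Adj, n: int) -> frozenset[frozenset[int]]:
    """Non-trivial unrooted splits; each as the leaf set opposite leaf 0."""
    out = set()
    for u, v in edges(adj):
        side = {x for x in _component(adj, u, v) if x < n}
        if 0 in side:
            side = set(range(n)) - side
        if 2 <= len(side) <= n - 2:
            out.add(frozenset(side))
    return frozenset(out)


def star_with_three(a: int, b: int, c: int, hub: int) -> Adj:
    return {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}


def insert_leaf_on_edge(adj: Adj, u: int, v: int, leaf: int, new_internal: int) -> Adj:
    """Subdivide edge (u, v) with ``new_internal`` and hang ``leaf`` on it."""
    out = copy_adj(adj)
    out[u][out[u].index(v)] = new_internal
    out[v][out[v].index(u)] = new_internal
    out[new_internal] = [u, v, leaf]
    out[leaf] = [new_internal]
    return out


def random_tree(n: int, rng: np.random.Generator) -> Adj:
    """Uniform stepwise random topology: leaves added on random edges."""
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nxt = n
    adj = star_with_three(0, 1, 2, nxt)
    nxt += 1
    for leaf in range(3, n):
        es = edges(adj)
        u, v = es[rng.integers(len(es))]
        adj = insert_leaf_on_edge(adj, u, v, leaf, nxt)
        nxt += 1
    return adj


def all_topologies(n: int) -> Iterator[Adj]:
    """Every unrooted binary topology on taxa 0..n-1 ((2n-5)!! of them)."""
    if n < 4:
        yield star_with_three(0, 1, 2, n) if n == 3 else {0: [1], 1: [0]}
        return

    def rec(adj: Adj, leaf: int, nxt: int) -> Iterator[Adj]:
        if leaf == n:
            yield adj
            return
        for u, v in edges(adj):
            yield from rec(insert_leaf_on_edge(adj, u, v, leaf, nxt),
                           leaf + 1, nxt + 1)

    yield from rec(star_with_three(0, 1, 2, n), 3, n + 1)


# ---------------------------------------------------------------------------
# rearrangements


def _remove_degree_two(adj: Adj, node: int) -> None:
    a, b = adj[node]
    adj[a][adj[a].index(node)] = b
    adj[b][adj[b].index(node)] = a
    del adj[node]


def spr_neighbors(adj: Adj) -> Iterator[Adj]:
    """Subtree pruning and regrafting: every subtree to every distant edge."""
    for u, v in list(edges(adj)):
        for root_side, anchor in ((v, u), (u, v)):
            if len(adj[anchor]) == 1:
                continue  # cutting here would isolate the anchor leaf
            pruned = copy_adj(adj)
            pruned[anchor].remove(root_side)
            pruned[root_side].remove(anchor)
            sub_nodes = _component(pruned, root_side, -1)
            _remove_degree_two(pruned, anchor)
            for x, y in edges(pruned):
                if x in sub_nodes or y in sub_nodes:
                    continue
                out = copy_adj(pruned)
                out[x][out[x].index(y)] = anchor
                out[y][out[y].index(x)] = anchor
                out[anchor] = [x, y, root_side]
                out[root_side] = out[root_side] + [anchor]
                yield out


def tbr_neighbors(adj: Adj) -> Iterator[Adj]:
    """Tree bisection-reconnection on internal edges, plus all SPR moves
    (which cover bisections at pendant edges)."""
    n_leaves = {k for k, v in adj.items() if len(v) == 1}
    for u, v in list(edges(adj)):
        if u in n_leaves or v in n_leaves:
            continue
        base = copy_adj(adj)
        base[u].remove(v)
        base[v].remove(u)
        comp_u = _component(base, u, -1)
        _remove_degree_two(base, u)
        _remove_degree_two(base, v)
        comp_u.discard(u)
        eu = [(x, y) for x, y in edges(base) if x in comp_u and y in comp_u]
        ev = [(x, y) for x, y in edges(base) if x not in comp_u and y not in comp_u]
        for ex in eu:
            for ey in ev:
                out = copy_adj(base)
                x1, y1 = ex
                out[x1][out[x1].index(y1)] = u
                out[y1][out[y1].index(x1)] = u
                out[u] = [x1, y1, v]
                x2, y2 = ey
                out[x2][out[x2].index(y2)] = v
                out[y2][out[y2].index(x2)] = v
                out[v] = [x2, y2, u]
                yield out
    yield from spr_neighbors(adj)


def nni_across_edge(adj: Adj, u: int, v: int, which: int = 0) -> Adj:
    """Nearest-neighbor interchange across internal edge (u, v)."""
    a = [w for w in adj[u] if w != v]
    b = [w for w in adj[v] if w != u]
    out = copy_adj(adj)
    swap_a, swap_b = a[0], b[which % len(b)]
    out[u][out[u].index(swap_a)] = swap_b
    out[v][out[v].index(swap_b)] = swap_a
    out[swap_a][out[swap_a].index(u)] = v
    out[swap_b][out[swap_b].index(v)] = u
    return out


# ---------------------------------------------------------------------------
# interchange with dendropy / newick


def to_newick(adj: Adj, taxa: list[str], root_leaf: int = 0) -> str:
    """Newick string rooted (for display) on the edge to ``root_leaf``."""
    start = adj[root_leaf][0]

    def rec(node: int, parent: int) -> str:
        if len(adj[node]) == 1:
            return taxa[node]
        kids = [rec(w, node) for w in adj[node] if w != parent]
        return "(" + ",".join(kids) + ")"

    return f"({taxa[root_leaf]},{rec(start, root_leaf)});"


def from_newick(newick: str, taxa: list[str]) -> Adj:
    """Parse a newick tree over the given taxon labels into adjacency form.

    The tree is read as unrooted (basal di/trichotomies collapsed)."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.migrate_taxon_namespace(dendropy.TaxonNamespace(taxa))
    index = {name: i for i, name in enumerate(taxa)}
    adj: Adj = {}
    nxt = len(taxa)
    node_id: dict = {}

    def get_id(nd) -> int:
        nonlocal nxt
        if nd in node_id:
            return node_id[nd]
        if nd.taxon is not None:
            node_id[nd] = index[nd.taxon.label]
        else:
            node_id[nd] = nxt
            nxt += 1
        return node_id[nd]

    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            a, b = get_id(nd), get_id(ch)
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
    # suppress the artificial root if it has degree 2
    root = node_id[tree.seed_node]
    if len(adj[root]) == 2:
        _remove_degree_two(adj, root)
    return adj


def strict_consensus_splits(trees: Iterable[Adj], n: int) -> frozenset:
    """Splits present in every tree of the collection."""
    it = iter(trees)
    first = next(it)
    out = set(splits(first, n))
    for t in it:
        out &= splits(t, n)
    return frozenset(out)
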