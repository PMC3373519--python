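"""Equally weighted Fitch parsimony: scoring, search, and clade support.

Tree length is the minimum number of unordered state changes summed over
characters (Fitch's intersect-else-union pass, vectorized over characters
with bitmask state sets).  The search is the classic heuristic: random
addition sequences to build a starting tree, then hill-climbing through
SPR or TBR rearrangements keeping up to ``hold`` equally parsimonious
trees per replicate.  Supports are nonparametric bootstrap proportions
(character resampling) and Bremer decay indices (converse-constraint
searches).  An outgroup, when given, is used only to root trees for
display — scoring and search are on unrooted topologies throughout.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np

from . import trees as T
from .characters import CharacterMatrix

__all__ = [
    "ParsimonyResult", "SupportValues", "fitch_length", "fitch_steps",
    "char_min_steps", "char_max_steps", "ci_ri", "random_addition_tree",
    "heuristic_search", "bootstrap_support", "bremer_support",
    "exhaustive_search",
]


@dataclasses.dataclass(frozen=True)
class ParsimonyResult:
    best_trees: tuple          # adjacency maps (see trees module)
    length: float              # integer-valued when weights are integral
    ci: float | None
    ri: float | None
    taxa: tuple
    search_log: dict

    @property
    def splits_consensus(self) -> frozenset:
        return T.strict_consensus_splits(self.best_trees, len(self.taxa))

    def newicks(self, root_taxon: str | None = None) -> list[str]:
        root = self.taxa.index(root_taxon) if root_taxon else 0
        return [T.to_newick(adj, list(self.taxa), root) for adj in self.best_trees]


@dataclasses.dataclass(frozen=True)
class SupportValues:
    """Per-bipartition support; splits keyed by frozensets of taxon labels
    (the side not containing the first taxon)."""
    values: dict
    kind: str  # "bootstrap" (percent) or "bremer" (extra steps)

    def get(self, clade: Iterable[str], default=None):
        return self.values.get(frozenset(clade), default)


# ---------------------------------------------------------------------------
# scoring


def _postorder(adj: T.Adj, root_leaf: int):
    """(node, parent) pairs, children before parents, rooted at the edge
    from ``root_leaf``."""
    start = adj[root_leaf][0]
    out, stack = [], [(start, root_leaf)]
    while stack:
        node, parent = stack.pop()
        out.append((node, parent))
        for w in adj[node]:
            if w != parent:
                stack.append((w, node))
    return out[::-1]


def fitch_steps(adj: T.Adj, masks: np.ndarray) -> np.ndarray:
    """Per-character Fitch step counts on an unrooted binary tree."""
    n, c = masks.shape
    root_leaf = next(k for k, v in adj.items() if len(v) == 1)
    steps = np.zeros(c, dtype=np.int64)
    node_mask: dict[int, np.ndarray] = {}
    for node, parent in _postorder(adj, root_leaf):
        if len(adj[node]) == 1:
            node_mask[node] = masks[node]
            continue
        kids = [w for w in adj[node] if w != parent]
        m1, m2 = node_mask[kids[0]], node_mask[kids[1]]
        inter = m1 & m2
        empty = inter == 0
        steps += empty
        node_mask[node] = np.where(empty, m1 | m2, inter)
        del node_mask[kids[0]], node_mask[kids[1]]
    top = node_mask[adj[root_leaf][0]]
    steps += (top & masks[root_leaf]) == 0
    return steps


def fitch_length(adj: T.Adj, matrix: CharacterMatrix,
                 weights: np.ndarray | None = None) -> float:
    """Weighted Fitch tree length; integral weights give an integer."""
    if set(T.leaves(adj)) != set(range(matrix.n_taxa)):
        raise ValueError("tree leaves do not match matrix taxa")
    w = matrix.weights if weights is None else np.asarray(weights, dtype=float)
    L = float(np.dot(fitch_steps(adj, matrix.masks), w))
    return round(L) if np.allclose(w, np.round(w)) else L


def _resolved_states(matrix: CharacterMatrix, j: int) -> list[int]:
    """Scored states of character j, polymorphisms resolved to their
    globally most frequent member state."""
    col = matrix.masks[:, j]
    full = matrix.full_mask
    freq = np.zeros(matrix.n_states, dtype=int)
    for cell in col:
        if cell == full:
            continue
        for s in range(matrix.n_states):
            if cell >> s & 1:
                freq[s] += 1
    out = []
    for cell in col:
        if cell == full:
            continue
        members = [s for s in range(matrix.n_states) if cell >> s & 1]
        out.append(max(members, key=lambda s: (freq[s], -s)))
    return out


def char_min_steps(matrix: CharacterMatrix, j: int) -> int:
    """Minimum conceivable steps m_j: distinct scored states minus one."""
    states = _resolved_states(matrix, j)
    return max(len(set(states)) - 1, 0)


def char_max_steps(matrix: CharacterMatrix, j: int) -> int:
    """Maximum steps g_j on any tree (unordered): scored taxa minus the
    frequency of the most common state."""
    states = _resolved_states(matrix, j)
    if len(states) <= 1:
        return 0
    counts = np.bincount(states)
    return int(len(states) - counts.max())


def ci_ri(tree_or_result, matrix: CharacterMatrix):
    """Consistency index sum(m)/L and retention index (sum(g)-L)/(sum(g)-sum(m)).

    RI is None when no character is informative (sum g == sum m).
    Values are never rounded here; round only for reporting.
    """
    if isinstance(tree_or_result, ParsimonyResult):
        L = tree_or_result.length
    else:
        L = fitch_length(tree_or_result, matrix)
    w = matrix.weights
    sm = float(sum(w[j] * char_min_steps(matrix, j)
                   for j in range(matrix.n_characters)))
    sg = float(sum(w[j] * char_max_steps(matrix, j)
                   for j in range(matrix.n_characters)))
    ci = sm / L if L > 0 else 1.0
    ri = (sg - L) / (sg - sm) if sg > sm else None
    return ci, ri


# ---------------------------------------------------------------------------
# search


def random_addition_tree(matrix: CharacterMatrix, rng: np.random.Generator,
                         weights: np.ndarray | None = None) -> T.Adj:
    """Greedy stepwise addition in a random taxon order (RAS start tree)."""
    n = matrix.n_taxa
    order = list(rng.permutation(n))
    nxt = n
    adj = T.star_with_three(order[0], order[1], order[2], nxt)
    nxt += 1
    for leaf in order[3:]:
        best, best_len = [], math.inf
        for u, v in T.edges(adj):
            cand = T.insert_leaf_on_edge(adj, u, v, leaf, nxt)
            # score on the taxa present so far: mask out absent leaves by
            # treating them as missing (they are not in the tree yet)
            ln = _partial_length(cand, matrix, weights)
            if ln < best_len - 1e-9:
                best, best_len = [cand], ln
            elif ln <= best_len + 1e-9:
                best.append(cand)
        adj = best[rng.integers(len(best))]
        nxt += 1
    return adj


def _partial_length(adj: T.Adj, matrix: CharacterMatrix,
                    weights: np.ndarray | None) -> float:
    w = matrix.weights if weights is None else weights
    return float(np.dot(fitch_steps(adj, matrix.masks), w))


def _hill_climb(adj: T.Adj, matrix: CharacterMatrix, swap: str, hold: int,
                weights: np.ndarray | None = None,
                forbid_split: frozenset | None = None):
    """Swap to a local optimum; returns (length, list of adj).

    ``forbid_split`` restricts the walk to trees lacking that split
    (converse-constraint mode for Bremer supports)."""
    n = matrix.n_taxa
    neighbor_fn = T.tbr_neighbors if swap == "tbr" else T.spr_neighbors

    def ok(a):
        return forbid_split is None or forbid_split not in T.splits(a, n)

    if not ok(adj):
        raise ValueError("start tree violates the converse constraint")
    cur_len = _partial_length(adj, matrix, weights)
    current = {T.splits(adj, n): adj}
    while True:
        improved = False
        added = False
        for a in list(current.values()):
            for nb in neighbor_fn(a):
                if not ok(nb):
                    continue
                ln = _partial_length(nb, matrix, weights)
                if ln < cur_len - 1e-9:
                    cur_len = ln
                    current = {T.splits(nb, n): nb}
                    improved = True
                    break
                if ln <= cur_len + 1e-9 and len(current) < hold:
                    key = T.splits(nb, n)
                    if key not in current:
                        current[key] = nb
                        added = True
            if improved:
                break
        if not improved and not added:
            return cur_len, list(current.values())


def heuristic_search(matrix: CharacterMatrix, replicates: int = 10,
                     swap: str = "tbr", hold: int = 10, seed: int = 0,
                     weights: np.ndarray | None = None,
                     compute_indices: bool = True) -> ParsimonyResult:
    """Random-addition + branch-swapping parsimony search.

    Pools all distinct optimal topologies over replicates; a fixed seed
    gives an identical result.
    """
    if matrix.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if swap not in ("tbr", "spr"):
        raise ValueError("swap must be 'tbr' or 'spr'")
    rng = np.random.default_rng(seed)
    n = matrix.n_taxa
    best_len = math.inf
    pool: dict = {}
    for _ in range(replicates):
        start = random_addition_tree(matrix, rng, weights)
        ln, local = _hill_climb(start, matrix, swap, hold, weights)
        if ln < best_len - 1e-9:
            best_len = ln
            pool = {}
        if ln <= best_len + 1e-9:
            for a in local:
                pool.setdefault(T.splits(a, n), a)
    best_trees = tuple(pool[k] for k in sorted(pool, key=sorted_key))
    L = round(best_len) if float(best_len).is_integer() else best_len
    ci = ri = None
    if compute_indices:
        ci, ri = ci_ri_from_length(L, matrix, weights)
    return ParsimonyResult(best_trees=best_trees, length=L, ci=ci, ri=ri,
                           taxa=matrix.taxa,
                           search_log={"replicates": replicates, "swap": swap,
                                       "hold": hold, "seed": seed})


def sorted_key(split_set: frozenset):
    return sorted(tuple(sorted(s)) for s in split_set)


def ci_ri_from_length(L, matrix, weights=None):
    w = matrix.weights if weights is None else np.asarray(weights, dtype=float)
    sm = float(sum(w[j] * char_min_steps(matrix, j)
                   for j in range(matrix.n_characters)))
    sg = float(sum(w[j] * char_max_steps(matrix, j)
                   for j in range(matrix.n_characters)))
    ci = sm / L if L > 0 else 1.0
    ri = (sg - L) / (sg - sm) if sg > sm else None
    return ci, ri


def exhaustive_search(matrix: CharacterMatrix,
                      weights: np.ndarray | None = None):
    """Score every unrooted topology (feasible for <= ~9 taxa)."""
    n = matrix.n_taxa
    best_len, best = math.inf, []
    for adj in T.all_topologies(n):
        ln = _partial_length(adj, matrix, weights)
        if ln < best_len - 1e-9:
            best_len, best = ln, [adj]
        elif ln <= best_len + 1e-9:
            best.append(adj)
    return best_len, best


# ---------------------------------------------------------------------------
# support


def _labelled(split: frozenset, taxa: Sequence[str]) -> frozenset:
    return frozenset(taxa[i] for i in split)


def bootstrap_support(matrix: CharacterMatrix, reps: int = 100,
                      search_cfg: dict | None = None,
                      seed: int = 0) -> SupportValues:
    """Bootstrap proportions: percent of character-resampled searches whose
    strict consensus contains each bipartition."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    cfg = {"replicates": 5, "swap": "spr", "hold": 5}
    cfg.update(search_cfg or {})
    rng = np.random.default_rng(seed)
    n, c = matrix.n_taxa, matrix.n_characters
    counts: dict = {}
    for _ in range(reps):
        wb = rng.multinomial(c, matrix.weights / matrix.weights.sum())
        res = heuristic_search(matrix, replicates=cfg["replicates"],
                               swap=cfg["swap"], hold=cfg["hold"],
                               seed=int(rng.integers(2**31)),
                               weights=wb.astype(float),
                               compute_indices=False)
        for split in res.splits_consensus:
            counts[split] = counts.get(split, 0) + 1
    values = {_labelled(s, matrix.taxa): 100.0 * k / reps
              for s, k in counts.items()}
    return SupportValues(values, "bootstrap")


def bremer_support(matrix: CharacterMatrix, best: ParsimonyResult,
                   clades: Iterable[frozenset] | None = None,
                   max_extra_steps: int = 20,
                   search_cfg: dict | None = None,
                   seed: int = 0) -> SupportValues:
    """Decay indices by converse-constraint searches: the shortest tree
    lacking each clade, minus the optimal length.  Values are capped at
    ``max_extra_steps``."""
    cfg = {"replicates": 10, "swap": "tbr", "hold": 5}
    cfg.update(search_cfg or {})
    n = matrix.n_taxa
    consensus = best.splits_consensus
    if clades is None:
        targets = list(consensus)
    else:
        targets = []
        for clade in clades:
            split = (frozenset(clade) if all(isinstance(x, int) for x in clade)
                     else frozenset(matrix.taxa.index(x) for x in clade))
            if split not in consensus:
                raise ValueError(f"clade {sorted(clade)} not in the strict "
                                 "consensus of best trees")
            targets.append(split)
    rng = np.random.default_rng(seed)
    values = {}
    for split in targets:
        best_con = math.inf
        for _ in range(cfg["replicates"]):
            start = random_addition_tree(matrix, rng)
            if split in T.splits(start, n):
                start = _break_split(start, split, n)
            ln, _ = _hill_climb(start, matrix, cfg["swap"], cfg["hold"],
                                forbid_split=split)
            best_con = min(best_con, ln)
        decay = min(best_con - best.length, max_extra_steps)
        values[_labelled(split, matrix.taxa)] = round(decay) \
            if float(decay).is_integer() else decay
    return SupportValues(values, "bremer")


def _break_split(adj: T.Adj, split: frozenset, n: int) -> T.Adj:
    """NNI across the edge inducing ``split`` (removes that bipartition)."""
    for u, v in T.edges(adj):
        if len(adj[u]) == 1 or len(adj[v]) == 1:
            continue
        side = {x for x in T._component(adj, u, v) if x < n}
        if 0 in side:
            side = set(range(n)) - side
        if frozenset(side) == split:
            return T.nni_across_edge(adj, u, v)
    raise ValueError("split not found on tree")
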