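"""Independent reference computations used to validate the main code paths.

Everything here is deliberately brute force: exhaustive enumeration of
lattice paths, of internal state assignments, of area assignments, and of
tree topologies.  None of it shares logic with the package's dynamic
programs or heuristics beyond the problem definitions themselves.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from numba import njit

from morphoclade import trees as T
from morphoclade._dp import DP_STEPS
from morphoclade.biogeo import AreaDistribution, split_scenarios, transition_cost


# ---------------------------------------------------------------------------
# elastic matching: exhaustive monotone lattice-path enumeration


@njit(cache=False)
def _enum_paths(q1, q2, steps, i, j, acc, m):
    if i == m - 1 and j == m - 1:
        return acc
    best = -1e30
    for s in range(steps.shape[0]):
        di, dj = steps[s, 0], steps[s, 1]
        ni, nj = i + di, j + dj
        if ni > m - 1 or nj > m - 1:
            continue
        lam = dj / di
        w = 0.0
        for a in range(1, di + 1):
            jf = j + a * lam
            jl = int(jf)
            if jl >= m - 1:
                jl = m - 2
            t = jf - jl
            ia = i + a
            w += (q1[ia, 0] * ((1 - t) * q2[jl, 0] + t * q2[jl + 1, 0])
                  + q1[ia, 1] * ((1 - t) * q2[jl, 1] + t * q2[jl + 1, 1]))
        w *= np.sqrt(lam) / m
        v = _enum_paths(q1, q2, steps, ni, nj, acc + w, m)
        if v > best:
            best = v
    return best


def brute_force_dp_objective(q1: np.ndarray, q2: np.ndarray) -> float:
    """Max of the warping objective over every monotone lattice path."""
    m = q1.shape[0]
    e0 = (q1[0, 0] * q2[0, 0] + q1[0, 1] * q2[0, 1]) / m
    return float(_enum_paths(q1, q2, DP_STEPS, 0, 0, e0, m))


# ---------------------------------------------------------------------------
# parsimony: exhaustive internal-state assignment


def brute_force_tree_length(adj: T.Adj, masks: np.ndarray) -> int:
    """Minimum changes over all assignments of single states to internal
    nodes (leaves may take any member of their state set)."""
    n_states = int(max(int(m).bit_length() for m in masks.ravel()))
    internals = [k for k, v in adj.items() if len(v) > 1]
    leaves = [k for k, v in adj.items() if len(v) == 1]
    edges = T.edges(adj)
    c = masks.shape[1]
    total = 0
    for j in range(c):
        best = math.inf
        leaf_choices = [
            [s for s in range(n_states) if masks[leaf, j] >> s & 1]
            for leaf in leaves
        ]
        for internal_states in itertools.product(range(n_states),
                                                 repeat=len(internals)):
            assign = dict(zip(internals, internal_states))
            for leaf_states in itertools.product(*leaf_choices):
                assign.update(zip(leaves, leaf_states))
                cost = sum(assign[u] != assign[v] for u, v in edges)
                if cost < best:
                    best = cost
        total += best
    return total


def exhaustive_best_length_lacking(matrix, split: frozenset) -> float:
    """Shortest Fitch length over all topologies missing a given split."""
    from morphoclade.parsimony import fitch_length

    n = matrix.n_taxa
    best = math.inf
    for adj in T.all_topologies(n):
        if split not in T.splits(adj, n):
            best = min(best, fitch_length(adj, matrix))
    return best


# ---------------------------------------------------------------------------
# DIVA: exhaustive assignment of ranges to internal nodes


def brute_force_diva(tree, ranges, areas, maxareas=None):
    """(cost, {clade: optimal bitsets}) by enumerating every assignment."""
    maxareas = len(areas) if maxareas is None else maxareas
    cands = [b for b in range(1, 1 << len(areas))
             if int(b).bit_count() <= maxareas]
    internal = list(tree.postorder_internal_node_iter())
    leafbits = {nd.taxon.label: ranges[nd.taxon.label].bits
                for nd in tree.leaf_node_iter()}
    scen = {F: split_scenarios(F) for F in cands}

    def bits_of(nd, assign):
        return leafbits[nd.taxon.label] if nd.is_leaf() else assign[id(nd)]

    best = math.inf
    opt: dict = {}
    for combo in itertools.product(cands, repeat=len(internal)):
        assign = {id(nd): b for nd, b in zip(internal, combo)}
        cost = 0
        for nd in internal:
            kids = nd.child_nodes()
            b0, b1 = bits_of(kids[0], assign), bits_of(kids[1], assign)
            cost += min(
                min(transition_cost(s1, b0) + transition_cost(s2, b1),
                    transition_cost(s2, b0) + transition_cost(s1, b1))
                for s1, s2 in scen[assign[id(nd)]])
        if cost < best:
            best = cost
            opt = {id(nd): {assign[id(nd)]} for nd in internal}
        elif cost == best:
            for nd in internal:
                opt[id(nd)].add(assign[id(nd)])
    by_clade = {}
    for nd in internal:
        clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        by_clade[clade] = frozenset(opt[id(nd)])
    return best, by_clade


# ---------------------------------------------------------------------------
# NMDS: direct textbook stress-1 recomputation


def textbook_stress1(D: np.ndarray, X: np.ndarray) -> float:
    """Kruskal stress-1 recomputed with an explicit PAVA implementation."""
    k = D.shape[0]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    deltas = np.array([D[i, j] for i, j in pairs])
    dists = np.array([np.linalg.norm(X[i] - X[j]) for i, j in pairs])
    order = np.argsort(deltas, kind="stable")
    y = dists[order]
    # pool adjacent violators
    blocks = [[v] for v in y]
    i = 0
    while i < len(blocks) - 1:
        m1 = sum(blocks[i]) / len(blocks[i])
        m2 = sum(blocks[i + 1]) / len(blocks[i + 1])
        if m1 > m2 + 1e-15:
            blocks[i] = blocks[i] + blocks.pop(i + 1)
            i = max(i - 1, 0)
        else:
            i += 1
    fitted = np.concatenate([[sum(b) / len(b)] * len(b) for b in blocks])
    dhat = np.empty_like(fitted)
    dhat[order] = fitted
    denom = float(np.sum(dists**2))
    if denom <= 0:
        return 1.0
    return float(np.sqrt(np.sum((dists - dhat) ** 2) / denom))


def random_range(rng: np.random.Generator, n_areas: int,
                 areas: tuple) -> AreaDistribution:
    return AreaDistribution(int(rng.integers(1, 1 << n_areas)), areas)
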