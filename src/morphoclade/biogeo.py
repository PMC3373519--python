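"""Exact dispersal-vicariance (event-cost) ancestral range reconstruction.

Ranges are subsets of a small ordered area list, encoded as bitsets.
Speciation is free when it partitions the ancestral range (vicariance,
any bipartition of a widespread range) or duplicates a single-area range
(within-area speciation); dispersal and extinction each cost one per area
added to or removed from a range along a branch.  A dynamic program over
all candidate ranges at every node finds the minimum total
dispersal+extinction cost and, per node, every range attaining it in at
least one globally optimal scenario — mirroring the alternative
reconstructions classic DIVA reports.
"""

from __future__ import annotations

import dataclasses
import math
from itertools import combinations
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "AreaDistribution", "DivaReconstruction", "transition_cost",
    "split_scenarios", "diva_reconstruct", "read_area_table",
]

DEFAULT_AREAS = ("E", "AS", "NNA", "SNA")  # Europe, Asia, N./S. North America


@dataclasses.dataclass(frozen=True)
class AreaDistribution:
    """A non-empty set of areas, held as a bitset over ``areas``."""

    bits: int
    areas: tuple

    def __post_init__(self):
        if self.bits <= 0:
            raise ValueError("empty area distribution")
        if self.bits >= 1 << len(self.areas):
            raise ValueError("bit outside the area list")
        object.__setattr__(self, "areas", tuple(self.areas))

    @classmethod
    def from_names(cls, names, areas=DEFAULT_AREAS) -> "AreaDistribution":
        bits = 0
        for nm in names:
            if nm not in areas:
                raise ValueError(f"unknown area {nm!r}")
            bits |= 1 << areas.index(nm)
        return cls(bits, tuple(areas))

    @property
    def names(self) -> tuple:
        return tuple(a for i, a in enumerate(self.areas) if self.bits >> i & 1)

    @property
    def size(self) -> int:
        return int(self.bits).bit_count()


def transition_cost(start, end) -> int:
    """Events along a branch: one per area gained (dispersal) or lost
    (extinction)."""
    b1 = start.bits if isinstance(start, AreaDistribution) else int(start)
    b2 = end.bits if isinstance(end, AreaDistribution) else int(end)
    if b1 <= 0 or b2 <= 0:
        raise ValueError("empty area distribution")
    return int(b1 ^ b2).bit_count()


def _bit_list(bits: int) -> list[int]:
    return [i for i in range(bits.bit_length()) if bits >> i & 1]


def split_scenarios(F) -> set[tuple[int, int]]:
    """Free speciation modes for a range F, as unordered daughter pairs.

    A single area duplicates; a widespread range splits into any
    bipartition of its areas (2^(k-1)-1 of them).
    """
    bits = F.bits if isinstance(F, AreaDistribution) else int(F)
    if bits <= 0:
        raise ValueError("empty area distribution")
    members = _bit_list(bits)
    if len(members) == 1:
        return {(bits, bits)}
    out = set()
    for r in range(1, len(members)):
        for sub in combinations(members, r):
            s1 = sum(1 << i for i in sub)
            s2 = bits ^ s1
            if (s2, s1) not in out:
                out.add((s1, s2))
    return out


@dataclasses.dataclass(frozen=True)
class DivaReconstruction:
    cost: int
    areas: tuple
    node_optima: dict          # clade (frozenset of taxon labels) -> tuple of bitsets
    tree: dendropy.Tree

    def optima_names(self, clade) -> tuple:
        key = frozenset(clade)
        return tuple(AreaDistribution(b, self.areas).names
                     for b in self.node_optima[key])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for clade, bitsets in self.node_optima.items():
            label = ";".join(sorted(clade))
            ranges = "|".join(
                "+".join(AreaDistribution(b, self.areas).names)
                for b in bitsets)
            rows.append((label, ranges))
        return pd.DataFrame(rows, columns=["clade", "optimal_ranges"])

    def annotated_newick(self) -> str:
        tree = self.tree.clone(depth=1)
        for nd in tree.preorder_internal_node_iter():
            clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            ranges = "|".join(
                "+".join(AreaDistribution(b, self.areas).names)
                for b in self.node_optima[clade])
            nd.label = ranges
        return tree.as_string(schema="newick", suppress_rooting=True)


def _candidate_sets(n_areas: int, maxareas: int) -> list[int]:
    return [b for b in range(1, 1 << n_areas)
            if int(b).bit_count() <= maxareas]


def diva_reconstruct(tree: dendropy.Tree | str,
                     terminal_ranges: Mapping[str, Sequence[str] | AreaDistribution],
                     areas: Sequence[str] = DEFAULT_AREAS,
                     maxareas: int | None = None) -> DivaReconstruction:
    """Minimum dispersal+extinction cost and all optimal ancestral ranges.

    ``tree`` is a rooted binary tree (dendropy Tree or newick string);
    ``terminal_ranges`` maps each leaf label to its observed areas.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick",
                                 preserve_underscores=True)
    areas = tuple(areas)
    ranges = {}
    for taxon, r in terminal_ranges.items():
        ranges[taxon] = (r if isinstance(r, AreaDistribution)
                         else AreaDistribution.from_names(r, areas))
    maxareas = len(areas) if maxareas is None else maxareas
    largest_tip = max(r.size for r in ranges.values())
    if maxareas < largest_tip:
        raise ValueError("maxareas smaller than a terminal range")
    cands = _candidate_sets(len(areas), maxareas)
    cost_tbl = {(a, b): transition_cost(a, b) for a in cands for b in cands}
    scen_tbl = {F: split_scenarios(F) for F in cands}

    up: dict = {}      # node -> {bits: best cost of the subtree}
    hmin: dict = {}    # node -> {start bits: min over G of trans+up}

    nodes = list(tree.postorder_node_iter())
    for nd in nodes:
        if nd.is_leaf():
            label = nd.taxon.label
            if label not in ranges:
                raise ValueError(f"no range for terminal {label!r}")
            up[nd] = {ranges[label].bits: 0}
        else:
            kids = nd.child_nodes()
            if len(kids) != 2:
                raise ValueError("tree must be binary; resolve polytomies "
                                 "before reconstruction")
            u = {}
            for F in cands:
                best = math.inf
                for s1, s2 in scen_tbl[F]:
                    c = min(hmin[kids[0]][s1] + hmin[kids[1]][s2],
                            hmin[kids[0]][s2] + hmin[kids[1]][s1])
                    if c < best:
                        best = c
                u[F] = best
            up[nd] = u
        hmin[nd] = {
            S: min(cost_tbl.get((S, G), transition_cost(S, G)) + cu
                   for G, cu in up[nd].items())
            for S in cands
        }

    root = tree.seed_node
    total = min(up[root].values())

    # top-down pass: down[node][G] = cost of everything outside the subtree
    # of ``node`` when that node has range G
    down: dict = {root: {F: 0 for F in up[root]}}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        kids = nd.child_nodes()
        for child, sib in ((kids[0], kids[1]), (kids[1], kids[0])):
            dd = {G: math.inf for G in cands}
            for F, dcost in down[nd].items():
                if dcost == math.inf:
                    continue
                for s1, s2 in scen_tbl[F]:
                    for sc, ss in ((s1, s2), (s2, s1)):
                        base = dcost + hmin[sib][ss]
                        if base == math.inf:
                            continue
                        for G in cands:
                            v = base + cost_tbl[(sc, G)]
                            if v < dd[G]:
                                dd[G] = v
            down[child] = dd

    node_optima = {}
    for nd in tree.preorder_internal_node_iter():
        clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        opt = tuple(sorted(F for F in up[nd]
                           if up[nd][F] + down[nd][F] == total))
        node_optima[clade] = opt
    return DivaReconstruction(cost=int(total), areas=areas,
                              node_optima=node_optima, tree=tree)


def read_area_table(path, areas: Sequence[str] = DEFAULT_AREAS) -> dict:
    """CSV ``taxon,areas`` with semicolon-separated area codes."""
    df = pd.read_csv(path)
    if not {"taxon", "areas"}.issubset(df.columns):
        raise ValueError("area table needs columns taxon, areas")
    return {str(r.taxon): AreaDistribution.from_names(
        [a.strip() for a in str(r.areas).split(";") if a.strip()], tuple(areas))
        for r in df.itertuples()}
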