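"""Synthetic data generators for every analysis stage.

Each generator is a pure function of its configuration and seed and
returns both the data and a truth table sufficient to recompute any
downstream expectation.  The outline generator draws tear-shaped closed
curves (the narial-outline morphology) at exact target length/width
ratios; the matrix generator places discrete state changes on the
branches of a known tree; the range generator simulates free
vicariance/duplication histories with a prescribed number of dispersal
and extinction events; the allometry generator draws from a linear
length-length model with Gaussian noise.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import trees as T
from .biogeo import AreaDistribution
from .characters import CharacterMatrix
from .curves import OutlineCurve, aspect_ratio

__all__ = [
    "OutlineGenConfig", "MatrixGenConfig", "RangeGenConfig",
    "gen_outlines", "gen_matrix", "gen_ranges", "gen_allometry",
    "teardrop", "random_rooted_tree",
    "DISTAL_TO_TOTAL_SLOPE", "HUMERUS_MM_TO_BODY_M_SLOPE",
]

# Anchor relationships for the two body-size regressions: a preserved
# distal humeral portion of 723 mm corresponds to a complete 803 mm
# element, and an 803 mm humerus to a 12.5 m animal.
DISTAL_TO_TOTAL_SLOPE = 803.0 / 723.0
HUMERUS_MM_TO_BODY_M_SLOPE = 12.5 / 803.0


# ---------------------------------------------------------------------------
# outlines


def teardrop(ratio: float, pointedness: float = 2.0, m: int = 256,
             label: str = "teardrop") -> OutlineCurve:
    """Closed tear-shaped outline rescaled to an exact length/width ratio.

    Base family x(t)=cos t, y(t)=w sin(t) sin^p(t/2); the sampled points
    are anisotropically rescaled along the principal axes so the measured
    aspect ratio equals ``ratio`` exactly.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    t = np.linspace(0.0, 2 * np.pi, m, endpoint=False)
    x = np.cos(t)
    y = np.sin(t) * np.sin(t / 2.0) ** pointedness
    pts = np.column_stack([x, y])
    # symmetric about the x axis, so principal axes are the coordinate axes
    ext_x = x.max() - x.min()
    ext_y = y.max() - y.min()
    pts[:, 1] *= (ext_x / ratio) / ext_y
    return OutlineCurve(label, pts, closed=True)


@dataclasses.dataclass(frozen=True)
class OutlineGenConfig:
    """groups: (label, target aspect ratio, pointedness, count)."""
    groups: tuple = (("mid_ratio", 2.4, 2.0, 10), ("high_ratio", 3.2, 2.0, 20))
    noise_sd: float = 0.02
    jitter_rotation: bool = True
    jitter_translation: bool = True
    jitter_scale: bool = True
    jitter_seed_shift: bool = True
    m_points: int = 256
    seed: int = 0

    def __post_init__(self):
        for g in self.groups:
            if g[1] < 1 or g[3] < 1:
                raise ValueError("ratios must be >= 1 and counts >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _smooth_noise(rng: np.random.Generator, m: int, sd: float,
                  scale: float, n_modes: int = 4) -> np.ndarray:
    """Band-limited periodic 2D perturbation with RMS amplitude sd*scale."""
    t = np.linspace(0.0, 2 * np.pi, m, endpoint=False)
    out = np.zeros((m, 2))
    for dim in range(2):
        f = np.zeros(m)
        for k in range(1, n_modes + 1):
            a, b = rng.normal(size=2) / k
            f += a * np.cos(k * t) + b * np.sin(k * t)
        out[:, dim] = f
    rms = np.sqrt(np.mean(out**2))
    if rms > 0:
        out *= sd * scale / rms
    return out


def gen_outlines(cfg: OutlineGenConfig = OutlineGenConfig()):
    """Tear-shaped outline sample; returns (curves, truth DataFrame)."""
    rng = np.random.default_rng(cfg.seed)
    curves, rows = [], []
    for label, ratio, pointed, count in cfg.groups:
        for i in range(count):
            name = f"{label}_{i:02d}"
            base = teardrop(ratio, pointed, cfg.m_points, name)
            pts = base.points.copy()
            scale = np.ptp(pts[:, 0])
            exact_ratio = aspect_ratio(base)
            if cfg.noise_sd > 0:
                pts = pts + _smooth_noise(rng, cfg.m_points, cfg.noise_sd, scale)
            theta, dx, dy, sfac, shift = 0.0, 0.0, 0.0, 1.0, 0
            if cfg.jitter_rotation:
                theta = float(rng.uniform(0, 2 * np.pi))
                R = np.array([[np.cos(theta), -np.sin(theta)],
                              [np.sin(theta), np.cos(theta)]])
                pts = pts @ R.T
            if cfg.jitter_scale:
                sfac = float(np.exp(rng.normal(scale=0.3)))
                pts = pts * sfac
            if cfg.jitter_translation:
                dx, dy = rng.normal(scale=2.0, size=2)
                pts = pts + (dx, dy)
            if cfg.jitter_seed_shift:
                shift = int(rng.integers(cfg.m_points))
                pts = np.roll(pts, shift, axis=0)
            curves.append(OutlineCurve(name, pts, closed=True))
            rows.append((name, label, ratio, exact_ratio, theta, dx, dy,
                         sfac, shift, cfg.seed))
    truth = pd.DataFrame(rows, columns=[
        "shape_id", "group", "target_ratio", "pre_noise_ratio", "rotation",
        "dx", "dy", "scale", "seed_shift", "seed"])
    return curves, truth


# ---------------------------------------------------------------------------
# character matrices


@dataclasses.dataclass(frozen=True)
class MatrixGenConfig:
    n_taxa: int = 8
    n_characters: int = 40
    n_states: int = 2
    change_budget: int = 1      # state changes per character; 1 = homoplasy-free
    missing_fraction: float = 0.0
    internal_edges_only: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.missing_fraction <= 1:
            raise ValueError("missing_fraction must be in [0, 1]")
        if self.n_characters < 1 or self.n_taxa < 4:
            raise ValueError("need >= 1 character and >= 4 taxa")


def gen_matrix(cfg: MatrixGenConfig = MatrixGenConfig(),
               true_tree: T.Adj | None = None):
    """Discrete matrix evolved on a known tree.

    Returns (matrix, true_tree adjacency, truth DataFrame with one row per
    change event).  With change_budget=1 and no missing data the matrix is
    homoplasy-free on the true tree by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_taxa
    tree = true_tree if true_tree is not None else T.random_tree(n, rng)
    all_edges = T.edges(tree)
    internal = [(u, v) for u, v in all_edges
                if len(tree[u]) > 1 and len(tree[v]) > 1]
    pool = internal if (cfg.internal_edges_only and internal) else all_edges
    masks = np.zeros((n, cfg.n_characters), dtype=np.uint32)
    rows = []
    root_leaf = 0
    for j in range(cfg.n_characters):
        k = min(cfg.change_budget, len(pool))
        chosen = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        events = {}
        for e_i, (u, v) in enumerate(chosen):
            new_state = 1 + (e_i % (cfg.n_states - 1)) if cfg.n_states > 1 else 0
            events[(u, v)] = new_state
            rows.append((j, u, v, new_state))
        # propagate states from the root leaf outward
        states = {}
        stack = [(tree[root_leaf][0], root_leaf, 0)]
        states[root_leaf] = 0
        while stack:
            node, parent, state = stack.pop()
            e = (min(node, parent), max(node, parent))
            if e in events:
                state = events[e]
            states[node] = state
            for w in tree[node]:
                if w != parent:
                    stack.append((w, node, state))
        for leaf in range(n):
            masks[leaf, j] = np.uint32(1 << states[leaf])
    full = np.uint32((1 << cfg.n_states) - 1)
    if cfg.missing_fraction > 0:
        miss = rng.random((n, cfg.n_characters)) < cfg.missing_fraction
        for i in range(n):  # keep every taxon scored somewhere
            if miss[i].all():
                miss[i, rng.integers(cfg.n_characters)] = False
        masks = np.where(miss, full, masks)
    taxa = tuple(f"t{i}" for i in range(n))
    matrix = CharacterMatrix(taxa, masks, cfg.n_states,
                             np.ones(cfg.n_characters),
                             np.zeros(cfg.n_characters, dtype=bool),
                             tuple(range(1, cfg.n_characters + 1)))
    truth = pd.DataFrame(rows, columns=["character", "edge_u", "edge_v",
                                        "new_state"])
    return matrix, tree, truth


# ---------------------------------------------------------------------------
# biogeographic ranges


def random_rooted_tree(n: int, rng: np.random.Generator):
    """Random rooted binary topology by uniform pairwise joins; returns a
    newick string over taxa r0..r{n-1}."""
    nodes = [f"r{i}" for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


@dataclasses.dataclass(frozen=True)
class RangeGenConfig:
    n_taxa: int = 8
    n_areas: int = 3
    n_dispersals: int = 0
    n_extinctions: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_areas < 2:
            raise ValueError("need >= 2 areas")
        if self.n_dispersals < 0 or self.n_extinctions < 0:
            raise ValueError("event counts must be >= 0")


def gen_ranges(cfg: RangeGenConfig = RangeGenConfig(),
               newick: str | None = None):
    """Forward-simulated range history; returns (newick, terminal ranges,
    event trace DataFrame).

    Speciation events are free vicariance/duplication; exactly
    ``n_dispersals`` area gains and ``n_extinctions`` area losses are
    inserted on random branches (re-drawn and logged when inapplicable,
    e.g. dispersal into a full range)."""
    rng = np.random.default_rng(cfg.seed)
    nw = newick if newick is not None else random_rooted_tree(cfg.n_taxa, rng)
    import dendropy
    tree = dendropy.Tree.get(data=nw, schema="newick")
    areas = tuple(chr(ord("A") + i) for i in range(cfg.n_areas))
    full = (1 << cfg.n_areas) - 1

    branches = [nd for nd in tree.preorder_node_iter()
                if nd.parent_node is not None]
    events = ([("dispersal", None)] * cfg.n_dispersals
              + [("extinction", None)] * cfg.n_extinctions)
    branch_events: dict = {id(b): [] for b in branches}
    for kind, _ in events:
        b = branches[rng.integers(len(branches))]
        branch_events[id(b)].append(kind)

    trace_rows = []
    ranges: dict = {}

    def clade_label(nd):
        return ";".join(sorted(lf.taxon.label for lf in nd.leaf_iter()))

    def simulate(nd, start_bits):
        bits = start_bits
        if nd.parent_node is not None:
            for kind in branch_events[id(nd)]:
                if kind == "dispersal":
                    absent = [i for i in range(cfg.n_areas)
                              if not bits >> i & 1]
                    if not absent:
                        trace_rows.append((kind, clade_label(nd), None,
                                           "resampled_full_range"))
                        continue
                    a = int(rng.choice(absent))
                    bits |= 1 << a
                    trace_rows.append((kind, clade_label(nd), areas[a], "ok"))
                else:
                    present = [i for i in range(cfg.n_areas) if bits >> i & 1]
                    if len(present) <= 1:
                        trace_rows.append((kind, clade_label(nd), None,
                                           "skipped_single_area"))
                        continue
                    a = int(rng.choice(present))
                    bits &= ~(1 << a)
                    trace_rows.append((kind, clade_label(nd), areas[a], "ok"))
        if nd.is_leaf():
            ranges[nd.taxon.label] = AreaDistribution(bits, areas)
            return
        kids = nd.child_nodes()
        if int(bits).bit_count() == 1:
            starts = (bits, bits)
            trace_rows.append(("duplication", clade_label(nd), None, "ok"))
        else:
            members = [i for i in range(cfg.n_areas) if bits >> i & 1]
            cut = int(rng.integers(1, len(members)))
            perm = rng.permutation(members)
            s1 = sum(1 << int(i) for i in perm[:cut])
            starts = (s1, bits ^ s1)
            trace_rows.append(("vicariance", clade_label(nd), None, "ok"))
        for kid, s in zip(kids, starts):
            simulate(kid, s)

    root_size = int(rng.integers(1, cfg.n_areas + 1))
    root_bits = sum(1 << int(i)
                    for i in rng.choice(cfg.n_areas, size=root_size,
                                        replace=False))
    simulate(tree.seed_node, root_bits)
    trace = pd.DataFrame(trace_rows,
                         columns=["event", "clade", "area", "status"])
    return nw, ranges, trace


# ---------------------------------------------------------------------------
# allometry


def gen_allometry(n: int = 12, slope: float = DISTAL_TO_TOTAL_SLOPE,
                  intercept: float = 0.0, sigma: float = 10.0,
                  x_range: tuple = (380.0, 760.0), seed: int = 0):
    """Paired lengths from y = intercept + slope*x + N(0, sigma^2).

    Returns (DataFrame with x, y, and the noiseless y_true; truth dict)."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(*x_range, size=n))
    y_true = intercept + slope * x
    y = y_true + rng.normal(scale=sigma, size=n) if sigma > 0 else y_true.copy()
    df = pd.DataFrame({"predictor_mm": x, "response": y, "response_true": y_true})
    truth = {"slope": slope, "intercept": intercept, "sigma": sigma,
             "seed": seed, "n": n}
    return df, truth
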