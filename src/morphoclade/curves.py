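"""Elastic shape analysis of 2D outline curves.

Curves are compared in the square-root velocity (SRV) representation
``q(t) = beta'(t) / sqrt(|beta'(t)|)``, which is translation invariant by
construction and made scale invariant by rescaling q to unit L2 norm.
Unit-norm SRVFs live on a sphere, where the geodesic distance between two
shapes is ``arccos <q1, q2>`` after optimizing out rotation, monotone
reparameterization and — for closed outlines — the starting point of the
parameterization.  The resulting dissimilarity feeds the ordination stage.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._dp import DP_STEPS, dp_match

__all__ = [
    "OutlineCurve",
    "SRVFCurve",
    "Reparameterization",
    "Rotation2D",
    "ShapeDistanceMatrix",
    "resample_curve",
    "to_srvf",
    "optimal_rotation",
    "optimal_reparam",
    "warp_srvf",
    "elastic_distance",
    "pairwise_distances",
    "aspect_ratio",
    "naris_ratio_state",
    "read_outlines_csv",
    "write_outlines_csv",
    "read_outlines_svg",
    "write_distance_matrix_csv",
    "read_distance_matrix_csv",
]


class InvalidCurveError(ValueError):
    """Raised for degenerate or malformed outline input."""


@dataclasses.dataclass(frozen=True)
class OutlineCurve:
    """An ordered 2D point sequence; ``closed`` joins last to first."""

    label: str
    points: np.ndarray  # (n, 2)
    closed: bool = True

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidCurveError(f"{self.label}: points must be (n, 2)")
        if pts.shape[0] < 4:
            raise InvalidCurveError(f"{self.label}: need at least 4 points")
        if not np.isfinite(pts).all():
            raise InvalidCurveError(f"{self.label}: non-finite coordinate")
        if _arc_lengths(pts, self.closed)[-1] <= 0:
            raise InvalidCurveError(f"{self.label}: zero total arc length")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def arc_length(self) -> float:
        return float(_arc_lengths(self.points, self.closed)[-1])


@dataclasses.dataclass(frozen=True)
class SRVFCurve:
    """Unit-norm square-root velocity function sampled on a uniform grid."""

    grid: np.ndarray  # (m,) in [0, 1]
    q: np.ndarray  # (m, 2)
    closed: bool

    def __post_init__(self):
        if self.q.shape[0] < 4:
            raise InvalidCurveError("SRVF needs at least 4 samples")
        nrm = srvf_norm(self.q)
        if abs(nrm - 1.0) > 1e-8:
            raise InvalidCurveError(f"SRVF norm {nrm} != 1")

    @property
    def m(self) -> int:
        return self.q.shape[0]


@dataclasses.dataclass(frozen=True)
class Reparameterization:
    """Monotone warp gamma: [0,1] -> [0,1] with fixed endpoints."""

    gamma: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.gamma, dtype=float)
        if np.any(np.diff(g) < -1e-12):
            raise ValueError("gamma must be non-decreasing")
        if abs(g[0]) > 1e-12 or abs(g[-1] - 1.0) > 1e-12:
            raise ValueError("gamma endpoints must be 0 and 1")
        object.__setattr__(self, "gamma", g)


@dataclasses.dataclass(frozen=True)
class Rotation2D:
    matrix: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.matrix, dtype=float)
        if not np.allclose(R @ R.T, np.eye(2), atol=1e-10):
            raise ValueError("rotation matrix not orthogonal")
        object.__setattr__(self, "matrix", R)

    @property
    def angle(self) -> float:
        return float(np.arctan2(self.matrix[1, 0], self.matrix[0, 0]))


@dataclasses.dataclass(frozen=True)
class ShapeDistanceMatrix:
    labels: tuple
    d: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.d, dtype=float)
        k = len(self.labels)
        if D.shape != (k, k):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(D, D.T, atol=1e-6):
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(D)).max() > 1e-8:
            raise ValueError("nonzero diagonal")
        if D.min() < -1e-12 or D.max() > np.pi + 1e-9:
            raise ValueError("entries outside [0, pi]")
        object.__setattr__(self, "d", D)
        object.__setattr__(self, "labels", tuple(self.labels))


# ---------------------------------------------------------------------------
# resampling and the SRV transform


def _arc_lengths(pts: np.ndarray, closed: bool) -> np.ndarray:
    p = np.vstack([pts, pts[:1]]) if closed else pts
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _resample_points(pts: np.ndarray, closed: bool, m: int,
                     offset: float = 0.0) -> np.ndarray:
    """Uniform arc-length resampling; ``offset`` (in [0,1), closed only)
    shifts the starting point by a fraction of total length."""
    s = _arc_lengths(pts, closed)
    L = s[-1]
    if L <= 0:
        raise InvalidCurveError("zero-length curve")
    p = np.vstack([pts, pts[:1]]) if closed else pts
    if closed:
        targets = (offset * L + np.arange(m) * L / m) % L
    else:
        targets = np.linspace(0.0, L, m)
    x = np.interp(targets, s, p[:, 0])
    y = np.interp(targets, s, p[:, 1])
    out = np.column_stack([x, y])
    if not closed:
        out[0], out[-1] = pts[0], pts[-1]
    return out


def resample_curve(curve: OutlineCurve, m: int) -> OutlineCurve:
    """Resample to exactly ``m`` points uniformly spaced in arc length."""
    if m < 4:
        raise InvalidCurveError("m must be >= 4")
    return OutlineCurve(curve.label, _resample_points(curve.points, curve.closed, m),
                        curve.closed)


def srvf_inner(q1: np.ndarray, q2: np.ndarray) -> float:
    """Discrete L2 inner product with uniform weights summing to 1."""
    return float(np.sum(q1 * q2) / q1.shape[0])


def srvf_norm(q: np.ndarray) -> float:
    return float(np.sqrt(np.sum(q * q) / q.shape[0]))


def _q_from_points(pts: np.ndarray, closed: bool) -> np.ndarray:
    m = pts.shape[0]
    if closed:
        v = (np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)) * (m / 2.0)
    else:
        v = np.gradient(pts, 1.0 / (m - 1), axis=0)
    speed = np.linalg.norm(v, axis=1)
    if speed.max() <= 0:
        raise InvalidCurveError("all-zero derivative")
    q = v / np.sqrt(np.maximum(speed, 1e-300))[:, None]
    return q / srvf_norm(q)


def to_srvf(curve: OutlineCurve, m: int | None = None) -> SRVFCurve:
    """SRV transform after uniform arc-length resampling (default: keep n)."""
    m = curve.n if m is None else m
    pts = _resample_points(curve.points, curve.closed, m)
    grid = np.arange(m) / m if curve.closed else np.linspace(0.0, 1.0, m)
    return SRVFCurve(grid=grid, q=_q_from_points(pts, curve.closed),
                     closed=curve.closed)


def curve_from_srvf(srvf: SRVFCurve) -> np.ndarray:
    """Integrate q|q| back to a point sequence (up to translation/scale)."""
    q = srvf.q
    m = q.shape[0]
    v = q * np.linalg.norm(q, axis=1)[:, None]
    pts = np.cumsum(v, axis=0) / m
    return pts - pts.mean(axis=0)


# ---------------------------------------------------------------------------
# alignment


def _rotation_terms(q1: np.ndarray, q2: np.ndarray) -> tuple[float, float]:
    a = float(np.sum(q1 * q2))
    c = float(np.sum(q1[:, 1] * q2[:, 0] - q1[:, 0] * q2[:, 1]))
    return a, c


def optimal_rotation(q1: SRVFCurve | np.ndarray, q2: SRVFCurve | np.ndarray,
                     allow_reflection: bool = False) -> Rotation2D:
    """SO(2) (optionally O(2)) matrix O maximizing <q1, O q2>.

    Closed form via the 2x2 SVD of the cross-covariance (Kabsch).
    """
    a1 = q1.q if isinstance(q1, SRVFCurve) else q1
    a2 = q2.q if isinstance(q2, SRVFCurve) else q2
    if a1.shape != a2.shape:
        raise ValueError("SRVF grids differ in size")
    A = a2.T @ a1  # maximize tr(O A)
    U, s, Vt = np.linalg.svd(A)
    O = (U @ Vt).T
    if not allow_reflection and np.linalg.det(O) < 0:
        D = np.diag([1.0, -1.0])
        O = (U @ D @ Vt).T
    elif allow_reflection:
        Or = (U @ np.diag([1.0, -1.0]) @ Vt).T
        if np.trace(Or @ A.T) > np.trace(O @ A.T):
            O = Or
    return Rotation2D(O)


def _rotated(q: np.ndarray, O: np.ndarray) -> np.ndarray:
    return q @ O.T


def optimal_reparam(q1: SRVFCurve | np.ndarray, q2: SRVFCurve | np.ndarray,
                    dp_limit: int = 512) -> Reparameterization:
    """Monotone warp of q2 onto q1 by dynamic programming.

    The search runs over lattice paths with slope in [1/4, 4]; larger grids
    than ``dp_limit`` are refused (quadratic memory).
    """
    a1 = q1.q if isinstance(q1, SRVFCurve) else q1
    a2 = q2.q if isinstance(q2, SRVFCurve) else q2
    if a1.shape != a2.shape:
        raise ValueError("SRVF grids differ in size")
    if a1.shape[0] > dp_limit:
        raise ResourceWarning(
            f"DP grid {a1.shape[0]} exceeds limit {dp_limit}; reduce m")
    _, gamma = dp_match(np.ascontiguousarray(a1), np.ascontiguousarray(a2),
                        DP_STEPS)
    return Reparameterization(gamma)


def warp_srvf(q: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Apply (q o gamma) sqrt(gamma') on the uniform grid, renormalized."""
    m = q.shape[0]
    idx = gamma * (m - 1)
    qx = np.interp(idx, np.arange(m), q[:, 0])
    qy = np.interp(idx, np.arange(m), q[:, 1])
    gdot = np.gradient(gamma, 1.0 / (m - 1))
    out = np.column_stack([qx, qy]) * np.sqrt(np.maximum(gdot, 0.0))[:, None]
    nrm = srvf_norm(out)
    if nrm <= 0:
        raise FloatingPointError("degenerate warp")
    return out / nrm


def _best_rotation_inner(q1: np.ndarray, q2: np.ndarray,
                         allow_reflection: bool) -> float:
    a, c = _rotation_terms(q1, q2)
    val = np.hypot(a, c)
    if allow_reflection:
        qr = q2.copy()
        qr[:, 1] *= -1.0
        ar, cr = _rotation_terms(q1, qr)
        val = max(val, np.hypot(ar, cr))
    return val / q1.shape[0]


def _alternate_rotation_reparam(q1: np.ndarray, q2: np.ndarray,
                                allow_reflection: bool, tol: float,
                                max_rounds: int) -> float:
    """Alternating rotation/reparameterization rounds; best inner product."""
    best = -np.inf
    m = q1.shape[0]
    gamma = np.linspace(0.0, 1.0, m)
    for _ in range(max_rounds):
        q2g = warp_srvf(q2, gamma)
        O = optimal_rotation(q1, q2g, allow_reflection).matrix
        val_rot = srvf_inner(q1, _rotated(q2g, O))
        q2r = _rotated(q2, O)
        gamma = optimal_reparam(q1, q2r).gamma
        val = max(val_rot, srvf_inner(q1, warp_srvf(q2r, gamma)))
        if not np.isfinite(val):
            raise FloatingPointError("non-finite alignment objective")
        if val <= best + tol:
            best = max(best, val)
            break
        best = val
    return best


def _align_one_direction(q1: np.ndarray, curve2: OutlineCurve, m: int,
                         seed_search: bool, allow_reflection: bool,
                         tol: float = 1e-8, max_rounds: int = 20,
                         n_seed_candidates: int = 4) -> float:
    """Best inner product <q1, O (q2 o gamma) sqrt(gamma')> for one ordering.

    For closed outlines the cyclic starting point is searched on the full
    integer grid; the top few local maxima are each refined to fractional
    offsets and carried through the rotation/reparameterization rounds, so
    the result does not depend on how the input happened to be cut.
    """
    q2 = to_srvf(curve2, m).q
    if not (seed_search and curve2.closed):
        return _alternate_rotation_reparam(q1, q2, allow_reflection, tol,
                                           max_rounds)
    scores = np.array([
        _best_rotation_inner(q1, np.roll(q2, -k, axis=0), allow_reflection)
        for k in range(m)
    ])
    prev_s, next_s = np.roll(scores, 1), np.roll(scores, -1)
    peaks = np.flatnonzero((scores >= prev_s) & (scores >= next_s))
    peaks = peaks[np.argsort(scores[peaks])[::-1][:n_seed_candidates]]

    def q_at(offset_grid_units: float) -> np.ndarray:
        off = (offset_grid_units % m) / m
        return to_srvf(OutlineCurve(curve2.label,
                                    _resample_points(curve2.points, True, m,
                                                     offset=off), True)).q

    best = -np.inf
    for k0 in peaks:
        res = minimize_scalar(
            lambda s: -_best_rotation_inner(q1, q_at(s), allow_reflection),
            bounds=(k0 - 1.0, k0 + 1.0), method="bounded",
            options={"xatol": 1e-4})
        # keep the exact integer roll unless the refined cut is truly better
        if -res.fun > scores[k0]:
            cand = q_at(float(res.x))
        else:
            cand = np.roll(q2, -int(k0), axis=0)
        best = max(best, _alternate_rotation_reparam(
            q1, cand, allow_reflection, tol, max_rounds))
    return best


def _canonical_cut(curve: OutlineCurve) -> OutlineCurve:
    """Re-cut a closed outline at the vertex farthest from the vertex
    centroid.  The choice is invariant to rotation, translation, uniform
    scaling and cyclic relabeling of the input points, which pins down the
    seam the reparameterization is anchored at."""
    if not curve.closed:
        return curve
    pts = curve.points
    i = int(np.argmax(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
    return OutlineCurve(curve.label, np.roll(pts, -i, axis=0), True)


def elastic_distance(a: OutlineCurve, b: OutlineCurve, m: int = 128,
                     closed_seed_search: bool | None = None,
                     allow_reflection: bool = False) -> float:
    """Geodesic shape distance on the pre-shape sphere (radians).

    Minimizes arccos of the SRVF inner product over rotation, monotone
    reparameterization and (for closed outlines) the cyclic starting point,
    by alternating optimization.  Both orderings of the pair are evaluated
    and the smaller distance returned, so the result is symmetric; closed
    curves are re-cut at a canonical vertex first, so it is also
    independent of where the input outlines happened to start.
    """
    if m < 16:
        raise ValueError("m must be >= 16")
    if closed_seed_search is None:
        closed_seed_search = a.closed and b.closed
    a = _canonical_cut(a)
    b = _canonical_cut(b)
    q1 = to_srvf(a, m).q
    q2 = to_srvf(b, m).q
    e1 = _align_one_direction(q1, b, m, closed_seed_search, allow_reflection)
    e2 = _align_one_direction(q2, a, m, closed_seed_search, allow_reflection)
    e = min(max(e1, e2), 1.0)
    return float(np.arccos(np.clip(e, -1.0, 1.0)))


def pairwise_distances(shapes: Sequence[OutlineCurve], m: int = 128,
                       closed_seed_search: bool = True,
                       allow_reflection: bool = False) -> ShapeDistanceMatrix:
    """Symmetric matrix of elastic distances; each pair computed once."""
    labels = [s.label for s in shapes]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate shape labels")
    if len(shapes) < 2:
        raise ValueError("need at least two shapes")
    k = len(shapes)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = elastic_distance(
                shapes[i], shapes[j], m=m,
                closed_seed_search=closed_seed_search,
                allow_reflection=allow_reflection)
    return ShapeDistanceMatrix(tuple(labels), D)


# ---------------------------------------------------------------------------
# simple outline descriptors


def aspect_ratio(curve: OutlineCurve) -> float:
    """Length/width ratio: extents along the two principal axes, larger
    over smaller.  This is the measure behind the narial length/width
    character (cut points 1.85 and 2.85)."""
    pts = curve.points - curve.points.mean(axis=0)
    _, s, Vt = np.linalg.svd(pts, full_matrices=False)
    proj = pts @ Vt.T
    ext = proj.max(axis=0) - proj.min(axis=0)
    lo, hi = min(ext), max(ext)
    if lo <= 1e-12 * max(hi, 1.0):
        raise InvalidCurveError("degenerate (collinear) outline")
    return float(hi / lo)


RATIO_STATES = ("below_1.85", "between_1.85_and_2.85", "above_2.85")


def naris_ratio_state(ratio: float) -> str:
    """Three-bin coding of the length/width ratio; the middle bin is the
    closed interval [1.85, 2.85]."""
    if not ratio > 0:
        raise ValueError("ratio must be positive")
    if ratio < 1.85:
        return RATIO_STATES[0]
    if ratio <= 2.85:
        return RATIO_STATES[1]
    return RATIO_STATES[2]


# ---------------------------------------------------------------------------
# I/O


def read_outlines_csv(path) -> list[OutlineCurve]:
    """Long-format CSV: shape_id, point_index, x, y (one row per vertex)."""
    df = pd.read_csv(path)
    required = {"shape_id", "point_index", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"outline CSV must have columns {sorted(required)}")
    curves = []
    for label, g in df.groupby("shape_id", sort=False):
        g = g.sort_values("point_index")
        if not np.all(np.diff(g["point_index"].to_numpy()) > 0):
            raise ValueError(f"{label}: point_index not strictly increasing")
        curves.append(OutlineCurve(str(label), g[["x", "y"]].to_numpy()))
    return curves


def write_outlines_csv(curves: Iterable[OutlineCurve], path) -> None:
    rows = []
    for c in curves:
        for i, (x, y) in enumerate(c.points):
            rows.append((c.label, i, x, y))
    pd.DataFrame(rows, columns=["shape_id", "point_index", "x", "y"]).to_csv(
        path, index=False)


def read_outlines_svg(path, samples_per_path: int = 256) -> list[OutlineCurve]:
    """Minimal SVG reader: polygon/polyline points and paths made of
    M/L/Z commands (absolute coordinates)."""
    import re
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()
    ns = {"svg": "http://www.w3.org/2000/svg"}
    curves: list[OutlineCurve] = []

    def strip(tag):
        return tag.rsplit("}", 1)[-1]

    idx = 0
    for el in root.iter():
        tag = strip(el.tag)
        if tag in ("polygon", "polyline"):
            nums = [float(v) for v in re.split(r"[\s,]+", el.get("points", "").strip()) if v]
            pts = np.array(nums).reshape(-1, 2)
            curves.append(OutlineCurve(el.get("id", f"svg_{idx}"), pts,
                                       closed=tag == "polygon"))
            idx += 1
        elif tag == "path":
            d = el.get("d", "")
            tokens = re.findall(r"[MLZml]|-?\d*\.?\d+(?:e[+-]?\d+)?", d)
            pts, closed, cmd = [], False, None
            for t in tokens:
                if t in "MLZmlz":
                    cmd = t.upper()
                    if cmd == "Z":
                        closed = True
                elif cmd in ("M", "L"):
                    pts.append(float(t))
            if len(pts) >= 8:
                arr = np.array(pts).reshape(-1, 2)
                arr = _resample_points(arr, closed, samples_per_path)
                curves.append(OutlineCurve(el.get("id", f"svg_{idx}"), arr,
                                           closed=closed))
                idx += 1
    return curves


def write_distance_matrix_csv(dm: ShapeDistanceMatrix, path) -> None:
    pd.DataFrame(dm.d, index=list(dm.labels), columns=list(dm.labels)).to_csv(path)


def read_distance_matrix_csv(path) -> ShapeDistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return ShapeDistanceMatrix(tuple(str(c) for c in df.columns),
                               df.to_numpy(dtype=float))
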