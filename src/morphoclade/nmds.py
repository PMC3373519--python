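"""Non-metric multidimensional scaling with Kruskal stress-1.

Dissimilarities enter only through their ranks: each iteration fits
monotone disparities to the current configuration distances by isotonic
regression, then moves the configuration by a Guttman transform.  The
first restart starts from the classical (Torgerson) metric solution, the
others from random Gaussian configurations; the embedding with the lowest
final stress wins.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .curves import ShapeDistanceMatrix

__all__ = ["Embedding", "fit_nmds", "stress"]


@dataclasses.dataclass(frozen=True)
class Embedding:
    labels: tuple
    coords: np.ndarray  # (k, p), centered
    stress: float
    n_restarts_used: int
    seed: int
    stress_history: tuple = ()  # per-iteration stress of the winning restart

    def __post_init__(self):
        if not (0.0 <= self.stress <= 1.0 + 1e-12):
            raise ValueError("stress outside [0, 1]")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if np.abs(self.coords.mean(axis=0)).max() > 1e-8:
            raise ValueError("coordinates not centered")

    def to_csv(self, path) -> None:
        import pandas as pd
        cols = [f"axis{i+1}" for i in range(self.coords.shape[1])]
        df = pd.DataFrame(self.coords, columns=cols)
        df.insert(0, "shape_id", list(self.labels))
        df.to_csv(path, index=False)

    def run_log(self) -> str:
        return json.dumps({"stress": self.stress, "seed": self.seed,
                           "restarts": self.n_restarts_used})


def _as_matrix(D) -> np.ndarray:
    if isinstance(D, ShapeDistanceMatrix):
        return D.d
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    if D.min() < 0:
        raise ValueError("negative dissimilarity")
    return D


def _disparities(dvec: np.ndarray, deltavec: np.ndarray) -> np.ndarray:
    """Isotonic (monotone non-decreasing) fit of configuration distances
    against the ranked input dissimilarities."""
    order = np.argsort(deltavec, kind="stable")
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(order.size), dvec[order])
    out = np.empty_like(fitted)
    out[order] = fitted
    return out


def stress(D, coords: np.ndarray) -> float:
    """Kruskal stress-1: sqrt(sum (d - dhat)^2 / sum d^2), with dhat the
    isotonic disparities.  A configuration with zero spread gets 1.0."""
    Dm = _as_matrix(D)
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != Dm.shape[0]:
        raise ValueError("configuration size does not match dissimilarities")
    dvec = pdist(coords)
    denom = float(np.sum(dvec**2))
    if denom <= 0:
        return 1.0
    deltavec = squareform(Dm, checks=False)
    dhat = _disparities(dvec, deltavec)
    return float(np.sqrt(np.sum((dvec - dhat) ** 2) / denom))


def _classical_mds(D: np.ndarray, p: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:p]
    w = np.clip(w[idx], 0.0, None)
    X = V[:, idx] * np.sqrt(w)
    # canonical sign: largest-magnitude coordinate of each axis positive,
    # so the start is equivariant under relabeling of the objects
    for j in range(X.shape[1]):
        i = np.argmax(np.abs(X[:, j]))
        if X[i, j] < 0:
            X[:, j] = -X[:, j]
    return X


def _guttman_update(X: np.ndarray, deltahat: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    d = squareform(pdist(X), checks=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 1e-12, squareform(deltahat, checks=False) / d, 0.0)
    B = -ratio
    B[np.diag_indices(n)] = ratio.sum(axis=1)
    return (B @ X) / n


def _single_run(D: np.ndarray, X: np.ndarray, max_iter: int, tol: float):
    deltavec = squareform(D, checks=False)
    best_X = X.copy()
    best_s = stress(D, X)
    history = [best_s]
    for _ in range(max_iter):
        dvec = pdist(best_X)
        if np.all(dvec <= 1e-14):
            break
        dhat = _disparities(dvec, deltavec)
        Xn = _guttman_update(best_X, dhat)
        s = stress(D, Xn)
        if s > best_s - tol:
            if s < best_s:
                best_s, best_X = s, Xn
                history.append(s)
            break
        best_s, best_X = s, Xn
        history.append(s)
    return best_s, best_X, history


def fit_nmds(D, p: int = 2, restarts: int = 8, seed: int = 0,
             max_iter: int = 300, tol: float = 1e-12) -> Embedding:
    """Best-of-``restarts`` NMDS embedding of a dissimilarity matrix.

    The reported stress sequence within each restart is non-increasing
    (iteration stops at the first non-improving Guttman step), and a fixed
    seed yields a bit-identical embedding.
    """
    labels = D.labels if isinstance(D, ShapeDistanceMatrix) else tuple(
        range(np.asarray(D).shape[0]))
    Dm = _as_matrix(D)
    k = Dm.shape[0]
    if not (1 <= p <= k - 1):
        raise ValueError("need 1 <= p <= k-1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    scale = max(Dm.max(), 1e-12)
    best_s, best_X, best_h = np.inf, None, ()
    for r in range(restarts):
        X0 = _classical_mds(Dm, p) if r == 0 else rng.normal(
            scale=scale, size=(k, p))
        s, X, h = _single_run(Dm, X0, max_iter, tol)
        if s < best_s:
            best_s, best_X, best_h = s, X, tuple(h)
    coords = best_X - best_X.mean(axis=0)
    return Embedding(labels=tuple(labels), coords=coords,
                     stress=min(float(best_s), 1.0),
                     n_restarts_used=restarts, seed=seed,
                     stress_history=best_h)
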