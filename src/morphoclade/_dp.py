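"""Compiled dynamic-programming kernel for elastic curve matching.

The reparameterization search maximizes the SRVF inner product
``<q1, (q2 o gamma) sqrt(gamma')>`` over monotone lattice paths on the
m x m sample grid, with local slopes restricted to [1/4, 4] through a
fixed step set of coprime moves.  Ties are broken toward the most
diagonal (identity-like) step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Coprime steps (di, dj) with slope dj/di in [1/4, 4], ordered so that the
# diagonal step is tried first (argmax keeps the first maximal candidate,
# which breaks ties toward the identity path).
DP_STEPS = np.array(
    [
        (1, 1),
        (2, 1), (1, 2),
        (3, 1), (1, 3), (3, 2), (2, 3),
        (4, 1), (1, 4), (4, 3), (3, 4),
    ],
    dtype=np.int64,
)


@njit(cache=False)
def _step_weight(q1, q2, i0, j0, di, dj, inv_m):
    """Integral of q1(t).q2(gamma(t)) sqrt(gamma') along one lattice step.

    q2 is linearly interpolated at the fractional indices the straight
    segment visits; the sqrt-slope factor is constant on the segment.
    """
    lam = dj / di
    slam = np.sqrt(lam)
    acc = 0.0
    for a in range(1, di + 1):
        jf = j0 + a * lam
        jl = int(jf)
        if jl >= q2.shape[0] - 1:
            jl = q2.shape[0] - 2
        w = jf - jl
        ia = i0 + a
        acc += (
            q1[ia, 0] * ((1.0 - w) * q2[jl, 0] + w * q2[jl + 1, 0])
            + q1[ia, 1] * ((1.0 - w) * q2[jl, 1] + w * q2[jl + 1, 1])
        )
    return acc * slam * inv_m


@njit(cache=False)
def dp_match(q1, q2, steps):
    """Best monotone path (0,0)->(m-1,m-1); returns (objective, gamma).

    gamma is the piecewise-linear warp evaluated on the full grid,
    gamma[0]=0, gamma[-1]=1.
    """
    m = q1.shape[0]
    neg = -1e30
    E = np.full((m, m), neg)
    back = np.full((m, m), -1, dtype=np.int64)
    inv_m = 1.0 / m
    E[0, 0] = (q1[0, 0] * q2[0, 0] + q1[0, 1] * q2[0, 1]) * inv_m
    n_steps = steps.shape[0]
    for i in range(1, m):
        for j in range(1, m):
            best = neg
            best_s = -1
            for s in range(n_steps):
                di = steps[s, 0]
                dj = steps[s, 1]
                i0 = i - di
                j0 = j - dj
                if i0 < 0 or j0 < 0:
                    continue
                if E[i0, j0] <= neg / 2:
                    continue
                val = E[i0, j0] + _step_weight(q1, q2, i0, j0, di, dj, inv_m)
                if val > best:
                    best = val
                    best_s = s
            E[i, j] = best
            back[i, j] = best_s
    # trace back the optimal path, then interpolate gamma on the grid
    path_i = np.empty(2 * m, dtype=np.int64)
    path_j = np.empty(2 * m, dtype=np.int64)
    k = 0
    i = m - 1
    j = m - 1
    while i > 0 or j > 0:
        path_i[k] = i
        path_j[k] = j
        s = back[i, j]
        if s < 0:
            break
        i -= steps[s, 0]
        j -= steps[s, 1]
        k += 1
    path_i[k] = 0
    path_j[k] = 0
    k += 1
    gamma = np.empty(m)
    # path is stored end->start; walk pairs and fill by linear interpolation
    for idx in range(k - 1, 0, -1):
        ia = path_i[idx]
        ja = path_j[idx]
        ib = path_i[idx - 1]
        jb = path_j[idx - 1]
        for ii in range(ia, ib + 1):
            t = (ii - ia) / (ib - ia)
            gamma[ii] = (ja + t * (jb - ja)) / (m - 1.0)
    gamma[0] = 0.0
    gamma[m - 1] = 1.0
    return E[m - 1, m - 1], gamma
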