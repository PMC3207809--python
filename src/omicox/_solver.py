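"""Inner coordinate-descent kernel for the penalized Cox path.

Solves the weighted elastic-net subproblem arising from the quadratic
(IRLS) approximation of the Breslow partial likelihood:

    min_b  1/2 sum_i w_i (z_i - x_i' b)^2 + lam * ||b||_1 + lam2 * ||b||_2^2

by cyclic soft-thresholding updates. Compiled with numba; ``X`` should be
Fortran-ordered so column sweeps are contiguous.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sweep(X, w, res, beta, lam, lam2, wx2, active_only):
    n, p = X.shape
    max_move = 0.0
    for k in range(p):
        if wx2[k] <= 0.0:
            continue
        bk = beta[k]
        if active_only and bk == 0.0:
            continue
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, k] * res[i]
        s += wx2[k] * bk
        if s > lam:
            bnew = (s - lam) / (wx2[k] + 2.0 * lam2)
        elif s < -lam:
            bnew = (s + lam) / (wx2[k] + 2.0 * lam2)
        else:
            bnew = 0.0
        d = bnew - bk
        if d != 0.0:
            for i in range(n):
                res[i] -= X[i, k] * d
            beta[k] = bnew
            move = abs(d) * np.sqrt(wx2[k])
            if move > max_move:
                max_move = move
    return max_move


@njit(cache=True)
def cd_enet(X, w, res, beta, lam, lam2, wx2, tol, max_sweeps):
    """Cyclic coordinate descent on the weighted elastic net.

    ``res`` holds the current residual z - X beta and is updated in
    place, as is ``beta``. ``wx2[k] = sum_i w_i x_ik^2``. After each full
    sweep the iteration restricts itself to the active (nonzero) set
    until it stabilizes, then re-checks all coordinates (glmnet-style).
    Convergence when the largest weighted coefficient move in a full
    sweep falls below ``tol``.
    """
    sweeps = 0
    while sweeps < max_sweeps:
        max_move = _sweep(X, w, res, beta, lam, lam2, wx2, False)
        sweeps += 1
        if max_move < tol:
            break
        while sweeps < max_sweeps:
            max_move = _sweep(X, w, res, beta, lam, lam2, wx2, True)
            sweeps += 1
            if max_move < tol:
                break
    return beta
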