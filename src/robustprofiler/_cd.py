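"""Numba coordinate-descent kernel for the observation-weighted elastic net.

Operates on pre-standardized data: columns of ``X`` have weighted mean 0 and
weighted variance 1 (so ``sum_i u_i x_ij^2 == W``, the total weight), and ``y``
has weighted mean 0.  The solved problem is

    min_b  0.5 * sum_i u_i (y_i - x_i' b)^2
           + lam * sum_j v_j * (delta*|b_j| + 0.5*(1-delta)*b_j^2)

Convergence uses the usual active-set strategy: after each full sweep the
iteration cycles over the current non-zero set until stable, then re-checks
all coordinates; it stops when a full sweep moves no coefficient by more
than ``tol``.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _sweep(X, r, u, v, beta, idx, W, lam, delta):
    """One coordinate-descent pass over the coordinates in ``idx``; updates
    ``beta`` and the residual ``r`` in place, returns the largest step."""
    n = X.shape[0]
    max_delta = 0.0
    for jj in range(idx.shape[0]):
        j = idx[jj]
        old = beta[j]
        rho = 0.0
        for i in range(n):
            rho += u[i] * X[i, j] * r[i]
        rho += W * old
        thr = lam * v[j] * delta
        if rho > thr:
            new = (rho - thr) / (W + lam * v[j] * (1.0 - delta))
        elif rho < -thr:
            new = (rho + thr) / (W + lam * v[j] * (1.0 - delta))
        else:
            new = 0.0
        diff = new - old
        if diff != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * diff
            beta[j] = new
            ad = abs(diff)
            if ad > max_delta:
                max_delta = ad
    return max_delta


@njit(cache=True)
def _objective(r, u, v, beta, lam, delta):
    obj = 0.0
    for i in range(r.shape[0]):
        obj += 0.5 * u[i] * r[i] * r[i]
    for j in range(beta.shape[0]):
        obj += lam * v[j] * (delta * abs(beta[j])
                             + 0.5 * (1.0 - delta) * beta[j] * beta[j])
    return obj


@njit(cache=True)
def cd_solve(X, y, u, v, lam, delta, beta, tol, max_sweeps):
    """Cyclic coordinate descent with incremental residual updates.

    ``beta`` is modified in place (warm start allowed).  Returns
    ``(n_sweeps, objective_trace)`` with one trace entry per sweep (full or
    active-set).
    """
    n, p = X.shape
    W = 0.0
    for i in range(n):
        W += u[i]

    r = y.copy()
    for j in range(p):
        bj = beta[j]
        if bj != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * bj

    all_idx = np.arange(p)
    trace = np.empty(max_sweeps)
    n_sweeps = 0
    while n_sweeps < max_sweeps:
        md = _sweep(X, r, u, v, beta, all_idx, W, lam, delta)
        trace[n_sweeps] = _objective(r, u, v, beta, lam, delta)
        n_sweeps += 1
        if md < tol:
            break
        active = np.flatnonzero(beta)
        if active.shape[0] == 0:
            continue
        while n_sweeps < max_sweeps:
            md_a = _sweep(X, r, u, v, beta, active, W, lam, delta)
            trace[n_sweeps] = _objective(r, u, v, beta, lam, delta)
            n_sweeps += 1
            if md_a < tol:
                break

    return n_sweeps, trace[:n_sweeps].copy()
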