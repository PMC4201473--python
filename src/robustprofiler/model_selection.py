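"""Hyperparameter selection for the local robust fits by k-fold CV.

A single (lambda, delta, h) triple is selected for all target samples: for
each triple and each fold, every validation sample is predicted by a local
model fit at its own modulator value on the training folds, and the triple
minimizing the mean validation squared error wins (ties break toward the
larger lambda, then the larger bandwidth -- the more regularized model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enet import (
    PenaltySpec,
    adaptive_weights_from_init,
    fit_weighted_enet,
    lambda_path,
)
from .kernels import KernelSpec, bandwidth_grid, kernel_weights
from .outliers import OutlierWeights, compute_sample_weights

__all__ = ["CVResult", "kfold_cv", "make_grid"]


@dataclass
class CVResult:
    """Grid, per-fold validation losses and the selected triple."""

    grid: list[tuple[float, float, float]]
    fold_losses: np.ndarray  # (n_triples, k) summed squared validation error
    mean_loss: np.ndarray
    selected: tuple[float, float, float]
    selected_index: int
    k: int


def make_grid(
    X: np.ndarray,
    y: np.ndarray,
    m: np.ndarray,
    n_lambda: int = 20,
    ratio: float = 1e-3,
    deltas=(0.1, 0.5, 0.9, 1.0),
    bandwidths=None,
    n_bandwidths: int = 8,
) -> list[tuple[float, float, float]]:
    """Cross product of a lambda path (anchored at the unweighted global
    lambda_max), delta values and a bandwidth grid."""
    u = np.ones(np.asarray(y).shape[0])
    lams = lambda_path(X, y, u, PenaltySpec(delta=1.0), n_lambda=n_lambda, ratio=ratio)
    hs = bandwidth_grid(m, n_points=n_bandwidths) if bandwidths is None else np.asarray(bandwidths, float)
    return [(float(l), float(d), float(h)) for d in deltas for h in hs for l in lams]


def _subset_weights(ow: OutlierWeights | None, idx: np.ndarray) -> np.ndarray | None:
    return None if ow is None else ow.weights[idx]


def _path_sse(
    Xtr, ytr, mtr, Xval, yval, mval, w_tr, delta, h, lams_desc,
    adaptive, normalize, tol, max_sweeps,
):
    """Summed squared validation error along a descending lambda path for one
    (delta, h) pair on one fold, warm-starting along the path."""
    spec = KernelSpec(h, normalize=normalize)
    sse = np.zeros(len(lams_desc))
    for v in range(Xval.shape[0]):
        K = kernel_weights(float(mval[v]), mtr, spec)
        u = K if w_tr is None else w_tr * K
        if not np.any(u > 0):
            continue
        # rows with numerically-zero weight contribute nothing to the fit
        # (zero-weight equivalence); dropping them shrinks the local problem
        live = u > u.max() * 1e-12
        Xl, yl, ul = Xtr[live], ytr[live], u[live]
        warm_init = None
        warm_ad = None
        for li, lam in enumerate(lams_desc):
            init = fit_weighted_enet(
                Xl, yl, ul, PenaltySpec(lam=lam, delta=delta),
                tol=tol, max_sweeps=max_sweeps, warm_start=warm_init,
            )
            warm_init = init.coefficients_std
            if adaptive and init.active_set.size:
                vw = adaptive_weights_from_init(init.coefficients_std)
                fit = fit_weighted_enet(
                    Xl, yl, ul,
                    PenaltySpec(lam=lam, delta=delta, adaptive_weights=vw),
                    tol=tol, max_sweeps=max_sweeps, warm_start=warm_ad,
                )
                warm_ad = fit.coefficients_std
            else:
                fit = init
            pred = fit.predict(Xval[v:v + 1])[0]
            sse[li] += (yval[v] - pred) ** 2
    return sse


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    m: np.ndarray,
    grid: list[tuple[float, float, float]],
    k: int = 3,
    seed: int | np.random.Generator = 0,
    outlier: OutlierWeights | str | None = None,
    adaptive: bool = True,
    kernel_normalize: bool = True,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
) -> CVResult:
    """Seeded k-fold CV over (lambda, delta, h) triples.

    Outlier weights are computed once on the full data handed in
    (``outlier='auto'``) and subset per fold; fold assignment depends only on
    (n, k, seed).
    """
    if not grid:
        raise ValueError("empty grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < 2 * k:
        raise ValueError("insufficient samples: need n >= 2k")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)

    ow = compute_sample_weights(X, y, seed=rng) if isinstance(outlier, str) else outlier

    # group triples by (delta, h); walk each lambda path once per fold
    groups: dict[tuple[float, float], list[tuple[float, int]]] = {}
    for idx, (lam, delta, h) in enumerate(grid):
        groups.setdefault((delta, h), []).append((lam, idx))
    for key in groups:
        groups[key].sort(key=lambda t: -t[0])

    fold_losses = np.zeros((len(grid), k))
    for f in range(k):
        val_idx = np.sort(folds[f])
        tr_idx = np.sort(np.concatenate([folds[g] for g in range(k) if g != f]))
        w_tr = _subset_weights(ow, tr_idx)
        for (delta, h), lam_list in groups.items():
            lams_desc = np.array([l for l, _ in lam_list])
            sse = _path_sse(
                X[tr_idx], y[tr_idx], m[tr_idx], X[val_idx], y[val_idx],
                m[val_idx], w_tr, delta, h, lams_desc,
                adaptive, kernel_normalize, tol, max_sweeps,
            )
            for (lam, idx), s in zip(lam_list, sse):
                fold_losses[idx, f] = s

    mean_loss = fold_losses.mean(axis=1)
    order = sorted(
        range(len(grid)),
        key=lambda i: (mean_loss[i], -grid[i][0], -grid[i][2]),
    )
    best = order[0]
    return CVResult(
        grid=list(grid),
        fold_losses=fold_losses,
        mean_loss=mean_loss,
        selected=tuple(grid[best]),
        selected_index=int(best),
        k=k,
    )
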