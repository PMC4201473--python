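"""Patient-specific analysis: local robust fits, prediction, biomarker tables.

For each target sample t the model is a weighted adaptive elastic net whose
observation weights are u_i = w_i * K_h(m_t, m_i): the Gaussian kernel
localizes the fit to the target's modulator neighborhood while the outlier
weight w_i caps the influence of contaminated samples.  Setting all w_i = 1
reproduces the non-robust varying-coefficient fit through the identical code
path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enet import FitResult, PenaltySpec, fit_adaptive_enet, fit_weighted_enet
from .kernels import KernelSpec, kernel_weights
from .outliers import OutlierWeights, compute_sample_weights

__all__ = [
    "TargetFit",
    "prescreen_by_variance",
    "fit_target",
    "fit_all_targets",
    "predict",
    "biomarker_frequency",
]


@dataclass
class TargetFit:
    """The varying-coefficient estimate evaluated at one target sample."""

    target_id: object
    modulator_value: float
    fit: FitResult
    combined_weights: np.ndarray


def prescreen_by_variance(X: np.ndarray, n_keep: int) -> tuple[np.ndarray, np.ndarray]:
    """Keep the ``n_keep`` columns of largest sample variance (ascending
    column index breaks ties); returns the reduced matrix and kept indices in
    original column order."""
    X = np.asarray(X, dtype=float)
    if n_keep <= 0:
        raise ValueError("invalid count: n_keep must be positive")
    p = X.shape[1]
    if n_keep > p:
        raise ValueError("invalid count: n_keep exceeds the number of features")
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(p)
    # stable sort on descending variance => ties broken by ascending index
    ranked = np.argsort(-var, kind="stable")[:n_keep]
    kept = np.sort(ranked)
    return X[:, kept], kept


def _combined_weights(
    m: np.ndarray,
    m_target: float,
    kernel: KernelSpec,
    outlier: OutlierWeights | None,
) -> np.ndarray:
    K = kernel_weights(m_target, m, kernel)
    if outlier is None:
        return K
    return outlier.weights * K


def fit_target(
    X: np.ndarray,
    y: np.ndarray,
    m: np.ndarray,
    target_index: int,
    kernel: KernelSpec,
    penalty: PenaltySpec,
    outlier: OutlierWeights | None = None,
    adaptive: bool = True,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
    target_id: object | None = None,
    m_target: float | None = None,
) -> TargetFit:
    """Fit the local model at one target.  ``m_target`` overrides the
    modulator value (used when predicting a new sample from training data);
    otherwise it is ``m[target_index]``."""
    m = np.asarray(m, dtype=float)
    if m_target is None:
        if not 0 <= target_index < m.shape[0]:
            raise IndexError("target_index out of range")
        m_target = float(m[target_index])
    u = _combined_weights(m, m_target, kernel, outlier)
    if u.sum() < 3.0:
        raise ValueError("neighborhood too small: effective sample below 3")
    if adaptive:
        fit = fit_adaptive_enet(
            X, y, u, lam=penalty.lam, delta=penalty.delta, gamma=penalty.gamma,
            tol=tol, max_sweeps=max_sweeps,
        )
    else:
        fit = fit_weighted_enet(X, y, u, penalty, tol=tol, max_sweeps=max_sweeps)
    return TargetFit(
        target_id=target_id if target_id is not None else target_index,
        modulator_value=m_target,
        fit=fit,
        combined_weights=u,
    )


def fit_all_targets(
    X: np.ndarray,
    y: np.ndarray,
    m: np.ndarray,
    kernel: KernelSpec,
    penalty: PenaltySpec,
    outlier: OutlierWeights | str | None = "auto",
    adaptive: bool = True,
    sample_ids=None,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
) -> list[TargetFit]:
    """One local fit per sample.  Outlier weights are computed once on
    [X | y] (``outlier='auto'``) and reused across all targets; pass an
    :class:`OutlierWeights` to reuse precomputed weights, or ``None`` for the
    non-robust fit."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    ow = compute_sample_weights(X, y, seed=seed) if isinstance(outlier, str) else outlier
    ids = sample_ids if sample_ids is not None else list(range(X.shape[0]))
    return [
        fit_target(
            X, y, m, t, kernel, penalty, outlier=ow, adaptive=adaptive,
            tol=tol, max_sweeps=max_sweeps, target_id=ids[t],
        )
        for t in range(X.shape[0])
    ]


def predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    m_train: np.ndarray,
    X_new: np.ndarray,
    m_new: np.ndarray,
    kernel: KernelSpec,
    penalty: PenaltySpec,
    outlier: OutlierWeights | str | None = "auto",
    adaptive: bool = True,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Predict new samples: each is assigned a fresh local model fit at its
    own modulator value from the training data only (no leakage), and scored
    as yhat = b0(m_new) + x_new' b(m_new)."""
    X_train = np.asarray(X_train, dtype=float)
    X_new = np.asarray(X_new, dtype=float)
    m_new = np.atleast_1d(np.asarray(m_new, dtype=float))
    if X_new.ndim != 2 or X_new.shape[1] != X_train.shape[1]:
        raise ValueError("schema mismatch: train and new feature counts differ")
    if X_new.shape[0] != m_new.shape[0]:
        raise ValueError("alignment: X_new rows and m_new length differ")
    ow = (
        compute_sample_weights(X_train, y_train, seed=seed)
        if isinstance(outlier, str)
        else outlier
    )
    out = np.empty(X_new.shape[0])
    for i, mt in enumerate(m_new):
        tf = fit_target(
            X_train, y_train, m_train, 0, kernel, penalty, outlier=ow,
            adaptive=adaptive, tol=tol, max_sweeps=max_sweeps, m_target=float(mt),
        )
        out[i] = tf.fit.predict(X_new[i:i + 1])[0]
    return out


def biomarker_frequency(
    fits: list[TargetFit],
    threshold: float = 0.80,
    feature_ids=None,
    zero_tol: float = 0.0,
) -> pd.DataFrame:
    """Per-feature selection frequency across target fits.

    A feature is flagged when its selection fraction is strictly greater than
    ``threshold`` (e.g., >80% of 150 models means selected in >120 of them).
    """
    if not fits:
        raise ValueError("need at least one target fit")
    coef = np.vstack([tf.fit.coefficients for tf in fits])
    counts = (np.abs(coef) > zero_tol).sum(axis=0)
    frac = counts / len(fits)
    ids = feature_ids if feature_ids is not None else list(range(coef.shape[1]))
    return pd.DataFrame(
        {
            "feature_id": ids,
            "selection_count": counts,
            "selection_fraction": frac,
            "flagged": frac > threshold,
        }
    )
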