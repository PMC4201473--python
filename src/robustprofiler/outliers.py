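"""Outlier detection and weighting in high-dimensional data.

The chain is: projection-pursuit robust PCA (robust loadings maximize a MAD
scale, so outliers do not attract the components) -> Minimum Volume Ellipsoid
location/scatter of the scores -> robust Mahalanobis distances -> per-sample
weights w_i in [0, 1] that cap the influence of samples beyond the chi-square
cutoff.  A per-dataset contamination score built from first-component
distances screens whole datasets (e.g., one per drug) for contamination.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RobustPCs",
    "MVEEstimate",
    "OutlierWeights",
    "ContaminationRanking",
    "madn",
    "robust_pca",
    "mve_estimate",
    "robust_distances",
    "outlier_weights",
    "compute_sample_weights",
    "contamination_score",
    "rank_datasets",
]

_MADN_CONST = 1.4826022185056018  # 1 / Phi^{-1}(3/4)


def madn(x: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    """Median absolute deviation, scaled to be consistent at the normal."""
    x = np.asarray(x, dtype=float)
    med = np.median(x, axis=axis, keepdims=axis is not None)
    return _MADN_CONST * np.median(np.abs(x - med), axis=axis)


@dataclass
class RobustPCs:
    """Projection-pursuit robust principal components.

    ``var_fraction`` is the cumulative fraction of total robust variance
    (sum of squared column MADs) explained after each component; ``k`` is the
    number of retained components.
    """

    scores: np.ndarray
    loadings: np.ndarray
    robust_scales: np.ndarray
    var_fraction: np.ndarray
    k: int
    center: np.ndarray
    column_scale: np.ndarray


@dataclass
class MVEEstimate:
    """Robust location and scatter from the Minimum Volume Ellipsoid."""

    center: np.ndarray
    scatter: np.ndarray
    consistency_factor: float


@dataclass
class OutlierWeights:
    """Per-sample outlier weights and the distances that produced them."""

    distances_sq: np.ndarray
    weights: np.ndarray
    cutoff: float
    df: int
    quantile_level: float = 0.95


@dataclass
class ContaminationRanking:
    """Datasets ordered by contamination score, most contaminated first."""

    order: np.ndarray
    flagged: np.ndarray
    threshold: float


# ---------------------------------------------------------------------------
# robust PCA by projection pursuit (Croux & Ruiz-Gazen construction)
# ---------------------------------------------------------------------------

def robust_pca(
    X: np.ndarray,
    var_explained: float = 0.95,
    seed: int | np.random.Generator = 0,
    scale: bool = True,
    max_components: int | None = None,
    n_extra_dirs: int = 10,
) -> RobustPCs:
    """Sequential robust PCA: each loading maximizes the MAD of the projected
    data over candidate directions (the centered data points themselves plus
    a few random directions), followed by deflation.

    Columns are centered by their median and, when ``scale`` is true, divided
    by their normalized MAD (SD fallback for MAD-degenerate columns), so
    heterogeneous scales -- e.g., expression levels next to a response column
    -- do not dominate the pursuit.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("invalid data: expected a 2-D matrix")
    n, p = X.shape
    if n < 3:
        raise ValueError("insufficient samples: need at least 3 rows")
    if not 0.0 < var_explained <= 1.0:
        raise ValueError("var_explained must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    center = np.median(X, axis=0)
    Xc = X - center
    col_mad = madn(Xc, axis=0)
    col_sd = Xc.std(axis=0)
    if np.all(col_sd <= 1e-12):
        raise ValueError("degenerate data: all columns are constant")
    scale_vec = np.ones(p)
    if scale:
        scale_vec = np.where(col_mad > 1e-12, col_mad, np.where(col_sd > 1e-12, col_sd, 1.0))
    X0 = Xc / scale_vec

    total = float(np.sum(madn(X0, axis=0) ** 2))
    if total <= 0:
        # heavy ties everywhere; fall back to classical total variance
        total = float(np.sum(X0.var(axis=0)))

    k_cap = min(n - 1, p)
    if max_components is not None:
        k_cap = min(k_cap, int(max_components))

    R = X0.copy()
    loadings: list[np.ndarray] = []
    scales: list[float] = []
    cum: list[float] = []
    explained = 0.0
    for _ in range(k_cap):
        norms = np.linalg.norm(R, axis=1)
        cand = R[norms > 1e-10] / norms[norms > 1e-10, None]
        extra = rng.standard_normal((n_extra_dirs, p))
        if loadings:
            V = np.column_stack(loadings)
            extra -= (extra @ V) @ V.T
        en = np.linalg.norm(extra, axis=1)
        extra = extra[en > 1e-10] / en[en > 1e-10, None]
        cand = np.vstack([cand, extra]) if cand.size else extra
        if cand.size == 0:
            break
        proj = cand @ R.T  # (n_cand, n)
        s = madn(proj, axis=1)
        best = int(np.argmax(s))
        if s[best] <= 1e-12:
            break
        v = cand[best].copy()
        if loadings:
            V = np.column_stack(loadings)
            v -= V @ (V.T @ v)
        nv = np.linalg.norm(v)
        if nv <= 1e-10:
            break
        v /= nv
        sc = float(madn(X0 @ v))
        loadings.append(v)
        scales.append(sc)
        explained += sc * sc
        # robust scales of projections are not bounded by the column-MAD
        # total, so the cumulative fraction is clipped at 1
        cum.append(min(explained / total, 1.0))
        R -= np.outer(R @ v, v)
        if var_explained < 1.0 and explained / total >= var_explained:
            break

    if not loadings:
        raise ValueError("degenerate data: no direction with positive robust scale")
    V = np.column_stack(loadings)
    return RobustPCs(
        scores=X0 @ V,
        loadings=V,
        robust_scales=np.asarray(scales),
        var_fraction=np.asarray(cum),
        k=V.shape[1],
        center=center,
        column_scale=scale_vec,
    )


# ---------------------------------------------------------------------------
# Minimum Volume Ellipsoid
# ---------------------------------------------------------------------------

def _mve_shorth_1d(z: np.ndarray) -> tuple[float, float]:
    """Exact univariate MVE: midpoint and half-length of the shortest
    interval containing ceil(n/2) points (first such interval on ties)."""
    zs = np.sort(z)
    n = zs.size
    h = math.ceil(n / 2)
    widths = zs[h - 1:] - zs[: n - h + 1]
    j = int(np.argmin(widths))
    return float((zs[j] + zs[j + h - 1]) / 2.0), float(widths[j] / 2.0)


def _eval_subset(Z, idx, h):
    """Score one (k+1)-subset: log-volume of its inflated ellipsoid covering
    h points, plus the pieces needed to build the estimate."""
    S = np.cov(Z[idx], rowvar=False)
    S = np.atleast_2d(S)
    m = Z[idx].mean(axis=0)
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        return None
    diff = Z - m
    sol = np.linalg.solve(L, diff.T)
    d2 = np.sum(sol * sol, axis=0)
    d2h = float(np.partition(d2, h - 1)[h - 1])
    if d2h <= 0:
        return None
    k = Z.shape[1]
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    logvol = logdet + k * math.log(d2h)
    return logvol, m, S, d2h


def _reweight(Z, center, scatter, k):
    """One-step hard-rejection reweighting at the chi2(0.975) radius with the
    standard truncation consistency correction."""
    q = stats.chi2.ppf(0.975, k)
    try:
        L = np.linalg.cholesky(scatter)
    except np.linalg.LinAlgError:
        return center, scatter, None
    sol = np.linalg.solve(L, (Z - center).T)
    d2 = np.sum(sol * sol, axis=0)
    keep = d2 <= q
    if keep.sum() < k + 2:
        return center, scatter, None
    c_rw = Z[keep].mean(axis=0)
    S_rw = np.atleast_2d(np.cov(Z[keep], rowvar=False))
    corr = 0.975 / stats.chi2.cdf(q, k + 2)
    S_rw *= corr
    try:
        np.linalg.cholesky(S_rw)
    except np.linalg.LinAlgError:
        return center, scatter, None
    return c_rw, S_rw, corr


def _median_calibrate(Z, center, scatter, k):
    """Chi-square-median consistency: rescale the scatter so the median
    squared distance equals the chi-square(k) median.  This pins the bulk of
    clean data to its nominal distribution even when k is large relative to
    n and the raw subset scatter is badly conditioned."""
    try:
        L = np.linalg.cholesky(np.atleast_2d(scatter))
    except np.linalg.LinAlgError:
        return scatter, 1.0
    sol = np.linalg.solve(L, (Z - center).T)
    med = float(np.median(np.sum(sol * sol, axis=0)))
    if med <= 0:
        return scatter, 1.0
    f = med / stats.chi2.ppf(0.5, k)
    return scatter * f, f


def mve_estimate(
    scores: np.ndarray,
    n_subsets: int = 500,
    seed: int | np.random.Generator = 0,
    reweight: bool = True,
    method: str = "subsample",
) -> MVEEstimate:
    """Minimum Volume Ellipsoid location/scatter of an n x k score matrix.

    ``method='subsample'`` draws ``n_subsets`` random (k+1)-subsets, inflates
    each subset's ellipsoid until it covers ceil(n/2) points and keeps the one
    of minimal volume; ``method='exact'`` enumerates every (k+1)-subset
    (feasible for small n only).  The winning scatter is rescaled by the
    chi-square-median consistency factor; a one-step reweighting (default)
    then restores efficiency at the normal model.  The univariate case is
    solved exactly by the shortest-half interval.
    """
    Z = np.asarray(scores, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, k = Z.shape
    if n <= k:
        raise ValueError("underdetermined scatter: need n >= k + 1 samples")
    h = math.ceil(n / 2)
    rng = np.random.default_rng(seed)

    if k == 1:
        c, half = _mve_shorth_1d(Z[:, 0])
        if half <= 0:
            half = max(float(np.std(Z[:, 0])), 1e-12)
        factor = 1.0 / stats.chi2.ppf(0.5, 1)
        scatter = np.array([[half * half * factor]])
        center = np.array([c])
        if reweight:
            center, scatter, corr = _reweight(Z, center, scatter, 1)
            if corr is not None:
                factor = corr
        scatter, med_f = _median_calibrate(Z, center, scatter, 1)
        return MVEEstimate(
            center=center, scatter=scatter, consistency_factor=factor * med_f
        )

    if method == "exact":
        n_comb = math.comb(n, k + 1)
        if n_comb > 200_000:
            raise ValueError("exact MVE enumeration infeasible for this size")
        subsets = itertools.combinations(range(n), k + 1)
    elif method == "subsample":
        subsets = (rng.choice(n, size=k + 1, replace=False) for _ in range(int(n_subsets)))
    else:
        raise ValueError("method must be 'subsample' or 'exact'")

    best = None
    for idx in subsets:
        res = _eval_subset(Z, np.asarray(idx), h)
        if res is None:
            continue
        if best is None or res[0] < best[0]:
            best = res
    if best is None:
        raise ValueError("underdetermined scatter: no non-singular subset found")

    _, m, S, d2h = best
    chi_med = stats.chi2.ppf(0.5, k)
    factor = d2h / chi_med
    scatter = S * factor
    center = m
    if reweight:
        center, scatter, corr = _reweight(Z, center, scatter, k)
        if corr is not None:
            factor = corr
    scatter = (scatter + scatter.T) / 2.0
    scatter, med_f = _median_calibrate(Z, center, scatter, k)
    return MVEEstimate(
        center=center, scatter=scatter, consistency_factor=float(factor * med_f)
    )


def robust_distances(scores: np.ndarray, mve: MVEEstimate) -> np.ndarray:
    """Squared robust Mahalanobis distances RD_i^2 of score rows from the MVE
    location, in the MVE scatter metric."""
    Z = np.asarray(scores, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    try:
        L = np.linalg.cholesky(np.atleast_2d(mve.scatter))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular scatter: cannot invert the MVE scatter") from exc
    sol = np.linalg.solve(L, (Z - mve.center).T)
    return np.sum(sol * sol, axis=0)


def outlier_weights(
    distances_sq: np.ndarray,
    df: int,
    quantile_level: float = 0.95,
    soft: bool = True,
) -> OutlierWeights:
    """Weights w_i = min(1, cutoff / RD_i^2) with cutoff the chi-square(df)
    quantile (soft capping); ``soft=False`` gives the hard 0/1 indicator."""
    d2 = np.asarray(distances_sq, dtype=float)
    if np.any(d2 < 0):
        raise ValueError("invalid data: squared distances must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    cutoff = float(stats.chi2.ppf(quantile_level, df))
    with np.errstate(divide="ignore"):
        w = np.where(d2 <= cutoff, 1.0, (cutoff / np.where(d2 > 0, d2, 1.0)) if soft else 0.0)
    return OutlierWeights(
        distances_sq=d2, weights=w, cutoff=cutoff, df=int(df), quantile_level=quantile_level
    )


def compute_sample_weights(
    X: np.ndarray,
    y: np.ndarray | None = None,
    var_explained: float = 0.95,
    seed: int | np.random.Generator = 0,
    quantile_level: float = 0.95,
    soft: bool = True,
    n_subsets: int = 500,
    scale: bool = True,
) -> OutlierWeights:
    """Full outlier-weight chain on [X | y]: robust PCA at the requested
    variance fraction, MVE of the scores, robust distances, capped weights.

    The number of components fed to the MVE is capped: (k+1)-point subsets
    must stay smaller than the ceil(n/2) coverage set (k <= n/2 - 1), and in
    the p >= n regime -- where every sample is an extreme point of the cloud
    and later projection-pursuit scores are strongly non-normal -- the
    chi-square calibration of the distances only survives in a
    low-dimensional score space, so k is further capped at n/15 there.
    """
    rng = np.random.default_rng(seed)
    M = np.asarray(X, dtype=float)
    if y is not None:
        yv = np.asarray(y, dtype=float)
        if yv.shape[0] != M.shape[0]:
            raise ValueError("alignment: X and y lengths differ")
        M = np.column_stack([M, yv])
    n, p_tot = M.shape
    k_mve = max(1, n // 2 - 1)
    if p_tot >= n:
        k_mve = max(1, min(k_mve, n // 15))
    rp = robust_pca(M, var_explained=var_explained, seed=rng, scale=scale,
                    max_components=k_mve)
    Z = rp.scores
    mve = mve_estimate(Z, n_subsets=n_subsets, seed=rng)
    d2 = robust_distances(Z, mve)
    return outlier_weights(d2, df=Z.shape[1], quantile_level=quantile_level, soft=soft)


# ---------------------------------------------------------------------------
# per-dataset contamination screening
# ---------------------------------------------------------------------------

def contamination_score(
    X: np.ndarray,
    y: np.ndarray,
    quantile_level: float = 0.95,
    seed: int | np.random.Generator = 0,
    multiplicity_adjust: bool = True,
) -> float:
    """Contamination criterion C of a dataset: mean positive exceedance of
    squared robust distances, computed on the first principal component of
    [X | y], over a chi-square(1) cutoff.

    The component is the classical (variance-maximizing) first PC of the
    robustly standardized data: outliers inflate variance and therefore
    attract the component, which is exactly what makes the score sensitive to
    them; the distances on the scores are robust (univariate MVE), so the
    outliers cannot mask themselves.  C is zero exactly when no sample
    exceeds the cutoff.  With ``multiplicity_adjust`` (default) the cutoff is
    the chi-square(1) quantile at level ``quantile_level**(1/n)``, i.e.
    calibrated so that a whole clean dataset of n samples stays below it with
    probability ``quantile_level`` -- without the adjustment the largest of n
    clean distances would essentially always exceed a per-sample 95% quantile
    and no dataset would ever score 0.
    """
    X = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    if X.shape[0] != yv.shape[0]:
        raise ValueError("alignment: X and y lengths differ")
    rng = np.random.default_rng(seed)
    M = np.column_stack([X, yv])
    center = np.median(M, axis=0)
    Mc = M - center
    col_mad = madn(Mc, axis=0)
    col_sd = Mc.std(axis=0)
    sc = np.where(col_mad > 1e-12, col_mad, np.where(col_sd > 1e-12, col_sd, 1.0))
    M0 = Mc / sc
    # top right-singular vector = variance-maximizing direction
    _, _, vt = np.linalg.svd(M0, full_matrices=False)
    z = M0 @ vt[0]
    n = z.size
    mve = mve_estimate(z, seed=rng)
    d2 = robust_distances(z, mve)
    level = quantile_level ** (1.0 / n) if multiplicity_adjust else quantile_level
    cutoff = stats.chi2.ppf(level, 1)
    return float(np.mean(np.clip(d2 - cutoff, 0.0, None)))


def rank_datasets(scores) -> ContaminationRanking:
    """Order datasets by contamination score (descending) and flag those with
    C above mean(C) + 2 * MAD(C)."""
    c = np.asarray(scores, dtype=float)
    if c.size < 1:
        raise ValueError("need at least one score")
    order = np.argsort(-c, kind="stable")
    mad = float(np.median(np.abs(c - np.median(c))))
    threshold = float(np.mean(c) + 2.0 * mad)
    flagged = c > threshold
    return ContaminationRanking(order=order, flagged=flagged, threshold=threshold)
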