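"""Monte Carlo study: varying-coefficient data with rowwise contamination.

The generator draws n samples with a serially correlated multivariate-normal
design (cov(x_j, x_k) = rho^|j-k|), a uniform modulator m ~ U(0,1), and a
response built from n_nonzero randomly placed coefficient functions
beta_j(m) plus Gaussian noise.  Contamination replaces, for a fraction of
training samples, the response and a random subset of predictor cells by
draws from N(mean, sd) -- emulating gross errors in both expression and
drug-response measurements.  Methods are scored by the true-positive and
true-negative rates of per-target support recovery and by the median squared
test error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from .enet import PenaltySpec
from .kernels import KernelSpec
from .model_selection import kfold_cv, make_grid
from .outliers import compute_sample_weights
from .profiler import TargetFit, fit_all_targets, predict, prescreen_by_variance

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "MetricsRecord",
    "generate_dataset",
    "contaminate",
    "evaluate_fit",
    "run_study",
    "tables_config",
    "DEFAULT_METHODS",
    "DESK_GRID",
]

_COEF_SHAPES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    # smooth monotone switch centered at m = 0.5
    "type1": lambda m: 1.0 / (1.0 + np.exp(-10.0 * (m - 0.5))),
    # smooth unimodal bump over [0, 1]
    "type2": lambda m: np.sin(np.pi * m),
    "constant": lambda m: np.ones_like(m),
}


@dataclass
class SimulationConfig:
    """Full description of the generator and contamination scheme."""

    n: int = 100
    p: int = 1000
    n_nonzero: int = 100
    rho: float = 0.5
    sigma: float = 1.0
    coef_type: str = "type1"
    contamination_fraction: float = 0.0
    contamination_mean: float = 5.0
    contamination_sd: float = 1.0
    n_contam_features: int = 10
    n_train: int = 75
    n_test: int = 25
    n_replicates: int = 100
    amplitude_range: tuple[float, float] = (1.0, 2.0)
    random_sign: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train + self.n_test != self.n:
            raise ValueError("config: n_train + n_test must equal n")
        if not 0 < self.n_nonzero <= self.p:
            raise ValueError("config: need 0 < n_nonzero <= p")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("config: contamination_fraction must lie in [0, 1]")
        if self.coef_type not in _COEF_SHAPES:
            raise ValueError("config: unknown coef_type %r" % (self.coef_type,))
        if not -1.0 < self.rho < 1.0:
            raise ValueError("config: rho must lie in (-1, 1)")
        if self.sigma < 0:
            raise ValueError("config: sigma must be non-negative")
        if self.n_contam_features > self.p:
            raise ValueError("config: n_contam_features exceeds p")


@dataclass
class SimulatedDataset:
    """One simulated dataset with its ground truth."""

    X: np.ndarray
    y: np.ndarray
    m: np.ndarray
    beta_true: Callable[[np.ndarray], np.ndarray]
    support: np.ndarray
    amplitudes: np.ndarray
    outlier_flags: np.ndarray
    contaminated_features: list
    train_idx: np.ndarray
    test_idx: np.ndarray
    config: SimulationConfig


@dataclass
class MetricsRecord:
    """Support-recovery rates and median squared test error of one fit."""

    true_positive_rate: float
    true_negative_rate: float
    prediction_error: float
    replicate_id: int = 0


def generate_dataset(config: SimulationConfig, replicate_seed: int | np.random.Generator = 0) -> SimulatedDataset:
    """Draw one clean dataset from the varying-coefficient model."""
    rng = np.random.default_rng(replicate_seed)
    n, p = config.n, config.p
    m = rng.uniform(0.0, 1.0, n)
    Z = rng.standard_normal((n, p))
    X = np.empty((n, p))
    X[:, 0] = Z[:, 0]
    c = np.sqrt(1.0 - config.rho**2)
    for j in range(1, p):
        X[:, j] = config.rho * X[:, j - 1] + c * Z[:, j]

    support = np.sort(rng.choice(p, size=config.n_nonzero, replace=False))
    lo, hi = config.amplitude_range
    amp = rng.uniform(lo, hi, config.n_nonzero)
    if config.random_sign:
        amp = amp * rng.choice([-1.0, 1.0], size=config.n_nonzero)
    shape = _COEF_SHAPES[config.coef_type]

    def beta_true(mvals):
        mv = np.atleast_1d(np.asarray(mvals, dtype=float))
        B = np.zeros((mv.shape[0], p))
        B[:, support] = shape(mv)[:, None] * amp[None, :]
        return B[0] if np.isscalar(mvals) or np.ndim(mvals) == 0 else B

    B = shape(m)[:, None] * amp[None, :]
    y = np.sum(X[:, support] * B, axis=1) + config.sigma * rng.standard_normal(n)

    perm = rng.permutation(n)
    train_idx = np.sort(perm[: config.n_train])
    test_idx = np.sort(perm[config.n_train:])
    return SimulatedDataset(
        X=X, y=y, m=m, beta_true=beta_true, support=support, amplitudes=amp,
        outlier_flags=np.zeros(n, dtype=bool), contaminated_features=[None] * n,
        train_idx=train_idx, test_idx=test_idx, config=config,
    )


def contaminate(
    data: SimulatedDataset,
    config: SimulationConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> SimulatedDataset:
    """Replace, for round(fraction * n) randomly chosen *training* samples,
    the response and ``n_contam_features`` random predictor cells by draws
    from N(contamination_mean, contamination_sd).  Test samples are never
    contaminated."""
    cfg = config if config is not None else data.config
    n_out = int(round(cfg.contamination_fraction * cfg.n))
    if n_out == 0:
        return data
    rng = np.random.default_rng(seed)
    X = data.X.copy()
    y = data.y.copy()
    flags = data.outlier_flags.copy()
    feats: list = list(data.contaminated_features)
    chosen = rng.choice(data.train_idx, size=n_out, replace=False)
    for i in np.sort(chosen):
        y[i] = rng.normal(cfg.contamination_mean, cfg.contamination_sd)
        cols = rng.choice(cfg.p, size=cfg.n_contam_features, replace=False)
        X[i, cols] = rng.normal(cfg.contamination_mean, cfg.contamination_sd, cols.size)
        flags[i] = True
        feats[i] = np.sort(cols)
    return replace(data, X=X, y=y, outlier_flags=flags, contaminated_features=feats)


def evaluate_fit(
    fits: list[TargetFit],
    predictions: np.ndarray,
    data: SimulatedDataset,
    kept_idx: np.ndarray | None = None,
    zero_tol: float = 1e-8,
    replicate_id: int = 0,
) -> MetricsRecord:
    """Score one fitted model: per-target support recovery against the
    screened-in true support, averaged over targets, plus the median squared
    error of the test predictions."""
    p = data.X.shape[1]
    kept = np.arange(p) if kept_idx is None else np.asarray(kept_idx)
    in_support = np.isin(kept, data.support)
    coef = np.vstack([tf.fit.coefficients for tf in fits])
    est = np.abs(coef) > zero_tol
    tp = float(est[:, in_support].mean()) if in_support.any() else float("nan")
    tn = float((~est[:, ~in_support]).mean()) if (~in_support).any() else float("nan")
    resid = data.y[data.test_idx] - np.asarray(predictions)
    pe = float(np.median(resid**2))
    return MetricsRecord(
        true_positive_rate=tp, true_negative_rate=tn, prediction_error=pe,
        replicate_id=replicate_id,
    )


def tables_config(
    contamination_fraction: float,
    contamination_sd: float = 1.0,
    coef_type: str = "type1",
) -> SimulationConfig:
    """The benchmark study conditions: n=100, p=1000 with 100 non-zero
    varying coefficients, 75/25 train/test split; contaminated samples carry
    N(5,1) replacements in 10 predictors (study 1) or N(5,5) replacements in
    20 predictors (study 2)."""
    return SimulationConfig(
        contamination_fraction=contamination_fraction,
        contamination_sd=contamination_sd,
        n_contam_features=10 if contamination_sd <= 1.0 else 20,
        coef_type=coef_type,
    )


DEFAULT_METHODS = (
    {"name": "robust", "robust": True},
    {"name": "nonrobust", "robust": False},
)

# desk-scale CV grid used by the Tables-style study: small enough to keep a
# full multi-level paired comparison within minutes on one CPU
DESK_GRID = {
    "n_lambda": 5,
    "ratio": 1e-2,
    "deltas": (0.5, 1.0),
    "bandwidth_factors": (0.15, 0.4),
}


def _one_replicate(
    data: SimulatedDataset,
    methods,
    prescreen: int,
    grid_spec: dict,
    cv_k: int,
    rng: np.random.Generator,
    replicate_id: int,
    tol: float,
    max_sweeps: int,
) -> list[dict]:
    tr, te = data.train_idx, data.test_idx
    Xtr_full, ytr, mtr = data.X[tr], data.y[tr], data.m[tr]
    n_keep = min(prescreen, data.X.shape[1])
    _, kept = prescreen_by_variance(Xtr_full, n_keep)
    Xtr = Xtr_full[:, kept]
    Xte = data.X[te][:, kept]

    factors = grid_spec.get("bandwidth_factors")
    bandwidths = None
    if factors is not None:
        rngm = float(np.ptp(mtr)) or 1.0
        bandwidths = [f * rngm for f in factors]
    grid = make_grid(
        Xtr, ytr, mtr,
        n_lambda=grid_spec.get("n_lambda", 5),
        ratio=grid_spec.get("ratio", 1e-2),
        deltas=grid_spec.get("deltas", (0.5, 1.0)),
        bandwidths=bandwidths,
    )

    rows = []
    ow_cache = None
    for meth in methods:
        robust = bool(meth.get("robust", True))
        if robust:
            if ow_cache is None:
                ow_cache = compute_sample_weights(
                    Xtr, ytr, seed=rng, soft=meth.get("soft", True)
                )
            ow = ow_cache
        else:
            ow = None
        # the grid search only needs losses accurate enough to rank triples;
        # the final fits below use the tighter tolerance
        cv = kfold_cv(
            Xtr, ytr, mtr, grid, k=cv_k, seed=rng, outlier=ow,
            tol=max(tol, 1e-4), max_sweeps=min(max_sweeps, 1000),
        )
        lam, delta, h = cv.selected
        kernel = KernelSpec(h)
        penalty = PenaltySpec(lam=lam, delta=delta)
        fits = fit_all_targets(
            Xtr, ytr, mtr, kernel, penalty, outlier=ow,
            tol=tol, max_sweeps=max_sweeps,
        )
        preds = predict(
            Xtr, ytr, mtr, Xte, data.m[te], kernel, penalty, outlier=ow,
            tol=tol, max_sweeps=max_sweeps,
        )
        rec = evaluate_fit(fits, preds, data, kept_idx=kept, replicate_id=replicate_id)
        rows.append(
            {
                "replicate": replicate_id,
                "method": meth.get("name", "robust" if robust else "nonrobust"),
                "tp": rec.true_positive_rate,
                "tn": rec.true_negative_rate,
                "pe": rec.prediction_error,
                "lambda": lam,
                "delta": delta,
                "bandwidth": h,
            }
        )
    return rows


def run_study(
    config: SimulationConfig,
    methods=DEFAULT_METHODS,
    n_replicates: int | None = None,
    seed: int = 0,
    prescreen: int = 200,
    grid_spec: dict | None = None,
    cv_k: int = 3,
    tol: float = 1e-5,
    max_sweeps: int = 5000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full Monte Carlo study: generate, contaminate, pre-screen, CV, fit,
    evaluate -- once per replicate per method (methods share each replicate's
    dataset, so comparisons are paired).

    Returns (per-replicate table, aggregate table of means with Monte Carlo
    standard errors).
    """
    n_rep = config.n_replicates if n_replicates is None else int(n_replicates)
    if n_rep < 1:
        raise ValueError("config: need at least one replicate")
    gs = dict(DESK_GRID)
    if grid_spec:
        gs.update(grid_spec)
    children = np.random.SeedSequence(seed).spawn(n_rep)
    rows: list[dict] = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        data = generate_dataset(config, rng)
        data = contaminate(data, seed=rng)
        rows.extend(
            _one_replicate(
                data, methods, prescreen, gs, cv_k, rng, r, tol, max_sweeps
            )
        )
    per_rep = pd.DataFrame(rows)
    agg = (
        per_rep.groupby("method")[["tp", "tn", "pe"]]
        .agg(["mean", "sem"])
        .reset_index()
    )
    agg.columns = ["method"] + ["%s_%s" % (a, b) for a, b in agg.columns[1:]]
    return per_rep, agg
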