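"""Bootstrapped elastic-net marker discovery and pairwise correlations.

For one drug, the response y is the AUC across cell lines and X holds the
(imputed, log10) protein and p-site abundances. The elastic net minimises

    (1/2n) ||y - X b - b0||^2 + lambda * (alpha ||b||_1 + (1-alpha)/2 ||b||_2^2)

with mixing alpha and strength lambda. Hyperparameters follow a two-stage
schedule: lambda is tuned by cross-validated MSE on a log-spaced path at
alpha = 0.05, then alpha is picked from {0.01, 0.05, 0.1} at that lambda.
With the tuned pair, 100 bootstrap resamples of the cell lines are refitted
and summarised per feature as the mean coefficient (zeros from unselected
models included) and the selection frequency — the volcano-plot coordinates
used to nominate markers. A negative mean coefficient means higher abundance
goes with lower AUC, i.e. a sensitivity marker.

The pairwise-correlation screen is the model-free counterpart: Pearson r of
every feature against every drug over pairwise-complete (non-imputed)
observations, keeping only pairs with more than eight complete observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

import warnings

from .dose_response import DrugResponseMatrix
from .preprocessing import AbundanceMatrix

logger = logging.getLogger("proteoscreen")


@dataclass
class ElasticNetConfig:
    alpha_grid: tuple[float, ...] = (0.01, 0.05, 0.1)
    alpha_for_lambda_search: float = 0.05
    n_bootstrap: int = 100
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-3
    cv_folds: int | None = None  # None: leave-one-out for n <= 20, else 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < a <= 1 for a in self.alpha_grid):
            raise ValueError("alpha grid values must lie in (0, 1]")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


@dataclass
class ElasticNetReport:
    table: pd.DataFrame  # per feature: mean_coefficient, selection_frequency,
    # direction
    lambda_: float
    alpha: float
    n_models: int


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD, matching the usual scaler convention
    safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / safe, mean, np.where(sd > 0, sd, np.inf)


def solve_elastic_net(
    X: np.ndarray, y: np.ndarray, lambda_: float, alpha: float,
    max_iter: int = 20000,
) -> np.ndarray:
    """Elastic-net coefficients, returned on the original feature scale.

    Features are standardised and y centred internally; constant features
    get coefficient 0. ``lambda_`` is the overall penalty strength and
    ``alpha`` the L1/L2 mix (alpha = 1: lasso, alpha = 0: ridge).
    """
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    Xs, _, sd = _standardize(X)
    yc = y - y.mean()
    if lambda_ == 0:
        beta_std, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = ElasticNet(
                alpha=lambda_, l1_ratio=alpha, fit_intercept=False,
                max_iter=max_iter, tol=1e-8,
            )
            model.fit(Xs, yc)
        beta_std = model.coef_
    return beta_std / sd


def _lambda_path(X: np.ndarray, y: np.ndarray, alpha: float,
                 config: ElasticNetConfig) -> np.ndarray:
    Xs, _, _ = _standardize(np.asarray(X, float))
    yc = y - y.mean()
    n = len(y)
    lam_max = np.abs(Xs.T @ yc).max() / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio,
                        config.n_lambdas)


def _cv_folds(n: int, config: ElasticNetConfig, rng: np.random.Generator):
    k = config.cv_folds or (n if n <= 20 else 5)
    order = rng.permutation(n)
    return [order[i::k] for i in range(k)]


def _cv_fold_errors(X, y, lambda_, alpha, folds) -> np.ndarray:
    """Per-fold CV mean squared errors."""
    errs = []
    for test in folds:
        train = np.setdiff1d(np.arange(len(y)), test)
        beta = solve_elastic_net(X[train], y[train], lambda_, alpha,
                                 max_iter=5000)
        intercept = y[train].mean() - X[train].mean(axis=0) @ beta
        pred = X[test] @ beta + intercept
        errs.append(np.mean((y[test] - pred) ** 2))
    return np.asarray(errs)


def _sparsest_within_se(fold_errors: np.ndarray) -> int:
    """Index of the sparsest model not worse than the best by > 1 paired SE.

    ``fold_errors`` rows are candidate models ordered from sparsest (largest
    penalty) to densest; columns are CV folds. Each candidate is compared to
    the CV-minimum model on the *same* folds (paired differences), which
    cancels the fold-difficulty variance that would otherwise swamp the
    comparison; the first candidate whose mean paired excess error is within
    one standard error of zero wins.
    """
    mean = fold_errors.mean(axis=1)
    best = int(np.argmin(mean))
    k = fold_errors.shape[1]
    for i in range(best + 1):
        diff = fold_errors[i] - fold_errors[best]
        se = diff.std(ddof=1) / np.sqrt(k) if k > 1 else 0.0
        if diff.mean() <= se:
            return i
    return best


def tune(X: np.ndarray, y: np.ndarray,
         config: ElasticNetConfig) -> tuple[float, float]:
    """Two-stage hyperparameter search: lambda at fixed alpha, then alpha.

    Both stages prefer the sparsest model that is statistically
    indistinguishable from the CV minimum: a one-standard-error rule on
    *paired* fold-error differences against the best model, which cancels
    shared fold-difficulty variance (see :func:`_sparsest_within_se`). On a
    null response this collapses to the near-empty large-lambda model; a
    real signal keeps lambda at the interior CV minimum. Cross-validation
    folds are leave-one-out for small panels (n <= 20, e.g. a 17-line
    panel) and 5-fold otherwise, assigned deterministically from the config
    seed.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if np.std(y) == 0:
        raise ValueError("response is constant; nothing to tune")
    n = len(y)
    k = config.cv_folds or (n if n <= 20 else 5)
    if n < 2 * k and k != n:
        raise ValueError(f"need at least {2 * k} samples for {k}-fold CV")
    rng = np.random.default_rng(config.seed)
    folds = _cv_folds(n, config, rng)
    path = _lambda_path(X, y, config.alpha_for_lambda_search, config)
    errs = np.stack([
        _cv_fold_errors(X, y, lam, config.alpha_for_lambda_search, folds)
        for lam in path
    ])  # path runs from the largest (sparsest) lambda down
    lambda_star = float(path[_sparsest_within_se(errs)])
    # alpha grid ordered sparsest first (largest L1 share)
    alphas = sorted(config.alpha_grid, reverse=True)
    errs_a = np.stack([
        _cv_fold_errors(X, y, lambda_star, a, folds) for a in alphas
    ])
    alpha_star = float(alphas[_sparsest_within_se(errs_a)])
    return lambda_star, alpha_star


def bootstrap_report(
    X: np.ndarray,
    y: np.ndarray,
    lambda_: float,
    alpha: float,
    config: ElasticNetConfig,
    feature_names: list[str] | None = None,
) -> ElasticNetReport:
    """Refit the tuned model on bootstrap resamples and aggregate.

    Mean coefficients average over all models including zeros; the selection
    frequency is the fraction of models with a nonzero coefficient.
    Resamples with constant y are redrawn (at most 10 attempts each).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    names = feature_names if feature_names is not None else [
        f"f{j}" for j in range(p)
    ]
    rng = np.random.default_rng(config.seed)
    coefs = np.zeros((config.n_bootstrap, p))
    kept = 0
    for _ in range(config.n_bootstrap):
        for _attempt in range(10):
            idx = rng.integers(0, n, size=n)
            if np.std(y[idx]) > 0:
                break
        else:
            logger.warning("bootstrap resample with constant response skipped")
            continue
        coefs[kept] = solve_elastic_net(X[idx], y[idx], lambda_, alpha,
                                        max_iter=5000)
        kept += 1
    coefs = coefs[:kept]
    mean_coef = coefs.mean(axis=0) if kept else np.zeros(p)
    freq = (coefs != 0).mean(axis=0) if kept else np.zeros(p)
    table = pd.DataFrame(
        {
            "mean_coefficient": mean_coef,
            "selection_frequency": freq,
            "direction": np.where(
                freq == 0, "",
                np.where(mean_coef < 0, "sensitivity", "resistance"),
            ),
        },
        index=pd.Index(names, name="feature"),
    )
    return ElasticNetReport(table=table, lambda_=lambda_, alpha=alpha,
                            n_models=kept)


def discover_markers(
    X: np.ndarray, y: np.ndarray, config: ElasticNetConfig,
    feature_names: list[str] | None = None,
) -> ElasticNetReport:
    """Tune then bootstrap: the full per-drug marker-discovery procedure."""
    lambda_star, alpha_star = tune(X, y, config)
    return bootstrap_report(X, y, lambda_star, alpha_star, config,
                            feature_names=feature_names)


def pairwise_correlations(
    features: AbundanceMatrix,
    response: DrugResponseMatrix,
    min_pairs: int = 8,
) -> pd.DataFrame:
    """Pearson correlation of every feature against every drug's AUC.

    Uses pairwise-complete observations of the *non-imputed* matrix; pairs
    with n <= ``min_pairs`` complete observations are excluded ("more than
    eight" means n >= 9 at the default). p-values come from the
    t-distribution transform of r and are reported, not used as a filter.
    """
    fvals = features.values
    shared = [s for s in fvals.columns if s in response.auc.columns]
    rows = []
    for drug in response.drugs:
        auc = response.auc.loc[drug, shared].to_numpy(dtype=float)
        auc_ok = ~np.isnan(auc)
        fblock = fvals[shared].to_numpy(dtype=float)
        for i, feat in enumerate(fvals.index):
            both = auc_ok & ~np.isnan(fblock[i])
            n = int(both.sum())
            if n <= min_pairs:
                continue
            x = fblock[i][both]
            if np.std(x) == 0 or np.std(auc[both]) == 0:
                continue
            r, p = stats.pearsonr(x, auc[both])
            rows.append({"feature": feat, "drug": drug, "r": float(r),
                         "n": n, "p": float(p)})
    return pd.DataFrame(rows, columns=["feature", "drug", "r", "n", "p"])
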