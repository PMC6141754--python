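"""Genomic prediction: GBLUP, BayesB and random-forest regression with
replicated k-fold cross-validation.

GBLUP fits y = mu + g + e with g ~ N(0, sigma_g^2 K) by REML on the training
block of the realized relationship matrix and predicts held-out genotypes
from the kinship cross-block (equivalent to marker ridge regression when K is
built from the same markers).  BayesB is a spike-and-slab whole-genome
regression -- each marker effect is exactly zero with probability 1 - pi or
drawn from a normal slab whose per-marker variance has a scaled-inverse
chi-square prior (marginally a scaled-t) -- sampled by Gibbs.  The
random-forest model delegates to scikit-learn with regression defaults of
500 trees and p/3 candidate features per split.

Cross-validation partitions genotypes into folds, refits per fold and scores
each replicate by the Pearson correlation between observed values and the
pooled validation predictions (per-fold averaging is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize

__all__ = [
    "PredictionModelSpec",
    "CVResult",
    "gblup_fit_predict",
    "bayesb_fit_predict",
    "rf_fit_predict",
    "cross_validate",
]


@dataclass
class PredictionModelSpec:
    """Which model to fit and its hyperparameters."""

    model: str = "GBLUP"                 # GBLUP | BayesB | RF
    # BayesB
    burn_in: int = 10_000
    iterations: int = 20_000
    thinning: int = 5
    pi: float = 0.5                      # prior marker-inclusion probability
    slab_df: float = 5.0
    r2_prior: float = 0.5                # prior share of variance explained
    # RF
    n_trees: int = 500
    max_features: float = 1.0 / 3.0
    min_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("GBLUP", "BayesB", "RF"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.n_trees < 1 or self.thinning < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 < self.pi <= 1.0):
            raise ValueError("pi must lie in (0, 1]")


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------

def gblup_fit_predict(
    y_train: np.ndarray,
    K: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    ridge: float = 1e-6,
) -> np.ndarray:
    """Predict test genetic values from a kinship over train + test genotypes.

    REML estimates (sigma_g^2, sigma_e^2) on the training block via the
    eigendecomposition of K_train; test predictions are the conditional mean
    mu + K_test,train (K_train + delta I)^-1 (y_train - mu).
    """
    y = np.asarray(y_train, dtype=float)
    Ktr = K[np.ix_(train_idx, train_idx)] + ridge * np.eye(len(train_idx))
    S, U = np.linalg.eigh(Ktr)
    if S.min() < -1e-8:
        raise ValueError("kinship not positive semidefinite")
    S = np.clip(S, 0.0, None)
    yt = U.T @ y
    ones_t = U.T @ np.ones(len(y))
    n = len(y)

    def neg_restricted(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = S + delta
        a = float(ones_t @ (ones_t / w))
        b = float(ones_t @ (yt / w))
        mu = b / a
        r = yt - mu * ones_t
        rss = float(r @ (r / w))
        return (n - 1) * np.log(rss) + np.sum(np.log(w)) + np.log(a)

    grid = np.linspace(-8.0, 8.0, 33)
    g0 = grid[int(np.argmin([neg_restricted(g) for g in grid]))]
    res = optimize.minimize_scalar(
        neg_restricted, bounds=(g0 - 1.0, g0 + 1.0), method="bounded"
    )
    delta = float(np.exp(res.x))
    w = S + delta
    a = float(ones_t @ (ones_t / w))
    b = float(ones_t @ (yt / w))
    mu = b / a
    alpha = U @ ((yt - mu * ones_t) / w)
    g_test = K[np.ix_(test_idx, train_idx)] @ alpha
    return mu + g_test


# ---------------------------------------------------------------------------
# BayesB
# ---------------------------------------------------------------------------

@njit(cache=True)
def _bayesb_gibbs(
    X, y, iterations, burn_in, thinning, pi, df_b, scale_b, df_e, scale_e, seed
):
    n, p = X.shape
    np.random.seed(seed)
    xx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xx[j] = s
    beta = np.zeros(p)
    sigma_b2 = np.full(p, scale_b)
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    e = y - mu
    sigma_e2 = 0.0
    for i in range(n):
        sigma_e2 += e[i] * e[i]
    sigma_e2 = sigma_e2 / n + 1e-8

    beta_sum = np.zeros(p)
    incl_sum = np.zeros(p)
    mu_sum = 0.0
    n_kept = 0

    for it in range(iterations):
        # intercept
        r_mean = 0.0
        for i in range(n):
            r_mean += e[i]
        r_mean = r_mean / n + mu
        mu_new = np.random.normal(r_mean, np.sqrt(sigma_e2 / n))
        shift = mu_new - mu
        for i in range(n):
            e[i] -= shift
        mu = mu_new

        for j in range(p):
            if xx[j] <= 0.0:
                continue
            b_old = beta[j]
            # rhs = x_j' (e + x_j b_old)
            rhs = 0.0
            for i in range(n):
                rhs += X[i, j] * e[i]
            rhs += xx[j] * b_old
            v = xx[j]
            s2 = sigma_b2[j]
            lam = v * s2 + sigma_e2
            log_odds = (
                np.log(pi / (1.0 - pi + 1e-12))
                + 0.5 * (np.log(sigma_e2) - np.log(lam))
                + 0.5 * rhs * rhs * s2 / (sigma_e2 * lam)
            )
            if log_odds > 35.0:
                include = True
            elif log_odds < -35.0:
                include = False
            else:
                prob = 1.0 / (1.0 + np.exp(-log_odds))
                include = np.random.random() < prob
            if include:
                C = v + sigma_e2 / s2
                b_new = np.random.normal(rhs / C, np.sqrt(sigma_e2 / C))
            else:
                b_new = 0.0
            if b_new != b_old:
                diff = b_old - b_new
                for i in range(n):
                    e[i] += X[i, j] * diff
                beta[j] = b_new
            # slab variance: scaled-inverse-chi-square update
            if include:
                ssq = scale_b * df_b + beta[j] * beta[j]
                sigma_b2[j] = ssq / np.random.chisquare(df_b + 1.0)
            else:
                sigma_b2[j] = scale_b * df_b / np.random.chisquare(df_b)
            if not np.isfinite(beta[j]) or not np.isfinite(sigma_b2[j]):
                return beta_sum, incl_sum, mu_sum, -1, it

        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma_e2 = (scale_e * df_e + sse) / np.random.chisquare(df_e + n)

        if it >= burn_in and (it - burn_in) % thinning == 0:
            n_kept += 1
            mu_sum += mu
            for j in range(p):
                beta_sum[j] += beta[j]
                if beta[j] != 0.0:
                    incl_sum[j] += 1.0
    return beta_sum, incl_sum, mu_sum, n_kept, iterations


@dataclass
class BayesBPosterior:
    beta_mean: np.ndarray
    inclusion_prob: np.ndarray
    mu_mean: float
    n_samples: int


def bayesb_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    spec: PredictionModelSpec | None = None,
) -> tuple[np.ndarray, BayesBPosterior]:
    """Spike-and-slab (BayesB) whole-genome regression via Gibbs sampling.

    Marker effect beta_j is zero with probability 1 - pi, otherwise normal
    with a per-marker variance carrying a scaled-inverse chi-square prior
    (df ``slab_df``), scaled so the prior genetic variance matches
    ``r2_prior`` of the phenotypic variance.  Predictions use posterior-mean
    effects.  Raises on a divergent (non-finite) chain state.
    """
    spec = spec or PredictionModelSpec(model="BayesB")
    X = np.ascontiguousarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    n, p = X.shape
    vy = float(np.var(y)) or 1.0
    mean_var_x = float(np.mean(np.var(X, axis=0))) or 1.0
    df_b = spec.slab_df
    e_slab = spec.r2_prior * vy / (spec.pi * mean_var_x * p)
    scale_b = e_slab * max(df_b - 2.0, 0.5) / df_b
    df_e = 5.0
    scale_e = (1.0 - spec.r2_prior) * vy * max(df_e - 2.0, 0.5) / df_e

    beta_sum, incl_sum, mu_sum, n_kept, last_it = _bayesb_gibbs(
        X,
        y,
        spec.iterations,
        spec.burn_in,
        spec.thinning,
        spec.pi,
        df_b,
        scale_b,
        df_e,
        scale_e,
        spec.seed % (2**31),
    )
    if n_kept < 0:
        raise RuntimeError(f"BayesB chain diverged at iteration {last_it}")
    beta = beta_sum / n_kept
    post = BayesBPosterior(
        beta_mean=beta,
        inclusion_prob=incl_sum / n_kept,
        mu_mean=mu_sum / n_kept,
        n_samples=n_kept,
    )
    preds = np.asarray(X_test, dtype=float) @ beta + post.mu_mean
    return preds, post


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

def rf_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    spec: PredictionModelSpec | None = None,
) -> np.ndarray:
    """Bagged regression trees with random feature subsampling per split."""
    import warnings

    from sklearn.ensemble import RandomForestRegressor

    spec = spec or PredictionModelSpec(model="RF")
    y = np.asarray(y_train, dtype=float)
    if np.ptp(y) == 0.0:
        warnings.warn("constant training response; returning constant", RuntimeWarning)
        return np.full(len(X_test), y[0])
    rf = RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_features=spec.max_features,
        min_samples_leaf=spec.min_leaf,
        random_state=spec.seed % (2**31),
        n_jobs=1,
    )
    rf.fit(np.asarray(X_train, dtype=float), y)
    return rf.predict(np.asarray(X_test, dtype=float))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    accuracies: np.ndarray       # one pooled accuracy per replicate
    mean: float
    se: float
    per_fold: pd.DataFrame       # replicate, fold, n_test, accuracy mode detail
    model: str
    seed: int


def _fit_predict(
    model_spec: PredictionModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    K: np.ndarray | None,
    train: np.ndarray,
    test: np.ndarray,
    seed: int,
) -> np.ndarray:
    spec = replace(model_spec, seed=seed)
    if spec.model == "GBLUP":
        from .popgen import kinship

        Kfull = kinship(X) if K is None else K
        return gblup_fit_predict(y[train], Kfull, train, test)
    if spec.model == "BayesB":
        preds, _ = bayesb_fit_predict(X[train], y[train], X[test], spec)
        return preds
    return rf_fit_predict(X[train], y[train], X[test], spec)


def cross_validate(
    model_spec: PredictionModelSpec,
    scores: np.ndarray,
    trait: np.ndarray | pd.Series,
    K: np.ndarray | None = None,
    folds: int = 10,
    replicates: int = 10,
    seed: int = 0,
    accuracy: str = "pooled",
) -> CVResult:
    """Replicated k-fold cross-validation accuracy.

    Per replicate, genotypes are randomly partitioned into ``folds`` folds;
    the model is refit on the remaining genotypes for each fold and the
    replicate's accuracy is the Pearson correlation between the observed
    values and the pooled validation predictions (``accuracy="per_fold"``
    averages per-fold correlations instead).  Mean and SE are taken over
    replicates.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(trait, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError("fewer genotypes than folds")
    if accuracy not in ("pooled", "per_fold"):
        raise ValueError(f"unknown accuracy mode {accuracy!r}")
    rng = np.random.default_rng(seed)
    if model_spec.model == "GBLUP" and K is None:
        from .popgen import kinship

        K = kinship(X)

    rep_acc = np.empty(replicates)
    detail = []
    for rep in range(replicates):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % folds
        preds = np.empty(n)
        fold_corrs = []
        for f in range(folds):
            test = np.flatnonzero(fold_of == f)
            train = np.flatnonzero(fold_of != f)
            if test.size < 2:
                raise ValueError("fold with < 2 genotypes; reduce folds")
            sub_seed = int(rng.integers(2**31))
            preds[test] = _fit_predict(model_spec, X, y, K, train, test, sub_seed)
            fc = _safe_corr(y[test], preds[test])
            fold_corrs.append(fc)
            detail.append(
                {"replicate": rep, "fold": f, "n_test": test.size, "accuracy": fc}
            )
        rep_acc[rep] = (
            _safe_corr(y, preds) if accuracy == "pooled" else float(np.nanmean(fold_corrs))
        )
    return CVResult(
        accuracies=rep_acc,
        mean=float(np.mean(rep_acc)),
        se=float(np.std(rep_acc, ddof=1) / np.sqrt(replicates)) if replicates > 1 else 0.0,
        per_fold=pd.DataFrame(detail),
        model=model_spec.model,
        seed=seed,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
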