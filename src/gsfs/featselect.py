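"""SNP feature selection by penalized regression and by p-value rank.

LASSO and elastic net minimize

    (1/(2n)) * ||y - mu - X b||^2 + lam * [ (1-alpha)/2 * ||b||^2
                                            + alpha * ||b||_1 ]

(the glmnet parameterization: ``alpha`` mixes the L1/L2 penalties,
``lam`` sets the strength).  Tuning follows the usual protocol: a
descending log-spaced lambda path per alpha, K-fold cross-validation,
the one-standard-error (1SE) rule within each alpha, and the alpha with
the smallest 1SE-rule CV error overall.  Columns are standardized to
unit variance inside each training set by default (penalty fairness
across allele frequencies) and coefficients are reported back on the
original genotype scale.

The coordinate-descent solver behind :func:`enet_fit` is scikit-learn's
``ElasticNet``; the path/CV/1SE machinery and the rank-by-p-value
comparator strategies live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet, enet_path

__all__ = [
    "RegularizationConfig",
    "FeatureSet",
    "enet_fit",
    "kkt_max_violation",
    "enet_objective",
    "cv_select_1se",
    "top_n_by_pvalue",
]


@dataclass(frozen=True)
class RegularizationConfig:
    """Tuning-protocol parameters for :func:`cv_select_1se`."""

    alpha_grid: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.96, 0.1), 2))
    n_folds: int = 10
    lambda_path_length: int = 100
    lambda_eps: float = 1e-3  # smallest lambda as a fraction of lambda_max
    fold_seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if not all(0 < a <= 1 for a in self.alpha_grid):
            raise ValueError("alpha values must lie in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("need at least 2 CV folds")
        if self.lambda_path_length < 2:
            raise ValueError("lambda path needs at least 2 values")


@dataclass
class FeatureSet:
    """Selected SNPs with provenance.

    ``snp_indices`` index into the design the selector saw; callers map
    them to genome-wide indices.  ``coefficients`` are nonzero for every
    listed SNP (effects on the original genotype scale for EN/LASSO,
    the GWAS effect for the rank-based strategies).
    """

    snp_indices: np.ndarray
    coefficients: np.ndarray
    strategy: str  # EN | LASSO | LMM_EN | LMM_LASSO
    alpha: float | None = None
    lam: float | None = None
    cv_curves: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.snp_indices = np.asarray(self.snp_indices, dtype=int)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.snp_indices.shape != self.coefficients.shape:
            raise ValueError("indices and coefficients must align")
        if np.any(self.coefficients == 0):
            raise ValueError("listed SNPs must have nonzero coefficients")

    @property
    def n_selected(self) -> int:
        return self.snp_indices.size


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd_safe
    Xs[:, sd == 0] = 0.0
    return Xs, mean, sd


def enet_fit(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    standardize: bool = False,
    tol: float = 1e-10,
    max_iter: int = 200_000,
) -> tuple[np.ndarray, float]:
    """Fit one elastic net at fixed (alpha, lam); returns (coef, intercept).

    With ``standardize=True`` the penalty applies to unit-variance
    columns and coefficients are back-transformed; zero-variance
    columns get coefficient 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in design or response")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if standardize:
        Xf, _, sd = _standardize(X)
    else:
        Xf, sd = X, None
    model = ElasticNet(
        alpha=lam, l1_ratio=alpha, fit_intercept=True,
        tol=tol, max_iter=max_iter,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter at tiny tol
        model.fit(Xf, y)
    coef = model.coef_.copy()
    intercept = float(model.intercept_)
    if standardize:
        nz = sd > 0
        coef[nz] = coef[nz] / sd[nz]
        coef[~nz] = 0.0
        intercept = float(y.mean() - X.mean(axis=0) @ coef)
    return coef, intercept


def enet_objective(
    X: np.ndarray, y: np.ndarray, coef: np.ndarray, intercept: float,
    alpha: float, lam: float,
) -> float:
    """The penalized objective value at (coef, intercept)."""
    n = y.shape[0]
    r = y - intercept - X @ coef
    return float(
        np.sum(r * r) / (2 * n)
        + lam * ((1 - alpha) / 2 * np.sum(coef**2) + alpha * np.sum(np.abs(coef)))
    )


def kkt_max_violation(
    X: np.ndarray, y: np.ndarray, coef: np.ndarray, intercept: float,
    alpha: float, lam: float,
) -> float:
    """Largest violation of the subgradient optimality conditions.

    For active coefficients the smooth gradient must equal
    ``-lam*alpha*sign(b)``; for inactive ones it must lie within
    ``[-lam*alpha, lam*alpha]``.  Returns the max excess over both.
    """
    n = y.shape[0]
    r = y - intercept - X @ coef
    grad = -(X.T @ r) / n + lam * (1 - alpha) * coef
    active = coef != 0
    viol_active = (
        np.abs(grad[active] + lam * alpha * np.sign(coef[active]))
        if active.any() else np.array([0.0])
    )
    viol_inactive = (
        np.maximum(np.abs(grad[~active]) - lam * alpha, 0.0)
        if (~active).any() else np.array([0.0])
    )
    viol_mu = abs(np.mean(r))  # intercept is unpenalized
    return float(max(viol_active.max(), viol_inactive.max(), viol_mu))


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest lambda at which every coefficient is zero."""
    n = y.shape[0]
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / (n * alpha))


def _fold_assignment(n: int, n_folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    folds = np.resize(np.arange(n_folds), n)
    return folds[rng.permutation(n)]


def _path_on_fold(
    X_tr, y_tr, X_va, y_va, alpha, lambdas, standardize
):
    """Validation MSE along a lambda path fit on one training fold."""
    if standardize:
        Xs, mean, sd = _standardize(X_tr)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Xv = (X_va - mean) / sd_safe
        Xv[:, sd == 0] = 0.0
    else:
        mean = X_tr.mean(axis=0)
        Xs, Xv = X_tr - mean, X_va - mean  # no intercept on the path
    yc = y_tr - y_tr.mean()
    _, coefs, _ = enet_path(
        Xs, yc, l1_ratio=alpha, alphas=lambdas, tol=1e-7, max_iter=20_000
    )
    pred = Xv @ coefs + y_tr.mean()
    return np.mean((pred - y_va[:, None]) ** 2, axis=0)


def cv_select_1se(
    X: np.ndarray,
    y: np.ndarray,
    config: RegularizationConfig | None = None,
    mode: str = "en",
) -> FeatureSet:
    """Cross-validated LASSO/EN selection with the 1SE rule.

    Per alpha: descending lambda path from lambda_max; K-fold CV mean
    and standard error of validation MSE; the 1SE lambda is the largest
    lambda whose mean CV error is within one SE of the minimum.  Across
    the alpha grid (a single alpha of 1 in lasso mode) the pair with
    the smallest 1SE-rule CV error wins; the model is refit on all data
    and nonzero coefficients returned.
    """
    if config is None:
        config = RegularizationConfig()
    if mode not in ("en", "lasso"):
        raise ValueError("mode must be 'en' or 'lasso'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < config.n_folds:
        raise ValueError("fewer observations than CV folds")
    alphas = (1.0,) if mode == "lasso" else config.alpha_grid
    folds = _fold_assignment(n, config.n_folds, config.fold_seed)

    if config.standardize:
        X_for_lmax, _, _ = _standardize(X)
    else:
        X_for_lmax = X
    curves: dict = {}
    best = None  # (cv_err_at_1se, alpha, lam)
    for alpha in alphas:
        lmax = lambda_max(X_for_lmax, y, alpha)
        if lmax == 0:
            continue
        lambdas = np.geomspace(lmax, config.lambda_eps * lmax,
                               config.lambda_path_length)
        fold_mse = np.empty((config.n_folds, lambdas.size))
        for k in range(config.n_folds):
            tr, va = folds != k, folds == k
            fold_mse[k] = _path_on_fold(
                X[tr], y[tr], X[va], y[va], alpha, lambdas,
                config.standardize,
            )
        mean = fold_mse.mean(axis=0)
        se = fold_mse.std(axis=0, ddof=1) / np.sqrt(config.n_folds)
        i_min = int(np.argmin(mean))
        thresh = mean[i_min] + se[i_min]
        i_1se = int(np.flatnonzero(mean <= thresh)[0])  # path is descending
        curves[alpha] = {
            "lambdas": lambdas, "mean": mean, "se": se,
            "i_min": i_min, "i_1se": i_1se,
        }
        if best is None or mean[i_1se] < best[0]:
            best = (mean[i_1se], float(alpha), float(lambdas[i_1se]))

    if best is None:
        warnings.warn("response has no correlation with any column; "
                      "empty selection")
        return FeatureSet(np.empty(0, int), np.empty(0), mode.upper(),
                          cv_curves=curves)
    _, alpha_star, lam_star = best
    coef, _ = enet_fit(
        X, y, alpha=alpha_star, lam=lam_star,
        standardize=config.standardize, tol=1e-8,
    )
    nz = np.flatnonzero(coef != 0)
    if nz.size == 0:
        warnings.warn("1SE-rule model selected no SNPs")
    strategy = "LASSO" if mode == "lasso" else "EN"
    return FeatureSet(
        snp_indices=nz,
        coefficients=coef[nz],
        strategy=strategy,
        alpha=alpha_star,
        lam=lam_star,
        cv_curves=curves,
    )


def top_n_by_pvalue(result, n: int, strategy: str = "LMM_LASSO") -> FeatureSet:
    """The n SNPs with the smallest scan p-values.

    Ties broken by larger |effect|, then by map order; untestable SNPs
    are never selected.  ``n`` is typically matched to a paired
    LASSO/EN selection size.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    table = result.table
    p = table["p_value"].to_numpy()
    beta = table["beta"].to_numpy()
    ok = np.isfinite(p)
    if n > ok.sum():
        raise ValueError(f"asked for {n} SNPs but only {ok.sum()} are testable")
    idx = np.flatnonzero(ok)
    # lexsort: last key is primary
    order = idx[np.lexsort((idx, -np.abs(beta[idx]), p[idx]))]
    chosen = np.sort(order[:n])
    return FeatureSet(
        snp_indices=chosen,
        coefficients=beta[chosen],
        strategy=strategy,
    )
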