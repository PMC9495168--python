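"""Single-marker linear mixed-model association scan.

Model per tested SNP: ``y = 1*mu + x*b + g + e`` with polygenic effect
``g ~ N(0, G_loco * sigma2_g)`` and residual ``e ~ N(0, I * sigma2_e)``,
where the polygenic covariance is a leave-one-chromosome-out (LOCO)
relationship matrix so the tested SNP never contributes to its own
null covariance.

Variance components are estimated once per LOCO null model by REML on
the GRM eigenbasis (a 1-D profile optimization over the variance ratio,
the EMMA device) and the ratio is held fixed for every SNP on that
chromosome; the total variance scale is re-estimated per SNP from the
weighted residual sum of squares, so forcing ``sigma2_g = 0`` reduces
the scan exactly to ordinary least-squares Wald tests.  The squared
effect/SE ratio is referred to a 1-df chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix
from .grm import GRM, grm_loco, imputed_codes

__all__ = [
    "NullModelFit",
    "GwasResult",
    "fit_null_reml",
    "fit_loco_nulls",
    "wald_scan",
    "preselect_by_threshold",
]

# The per-SNP-standardized GRM's distinct diagonal perturbs the zero
# eigenvalues of its centered Gram part, so small negative eigenvalues
# are expected (shrinking as the marker count grows); they are clipped
# to zero.  A matrix whose negative eigenvalue mass is a sizeable
# fraction of its positive mass is genuinely indefinite and rejected.
_NEG_MASS_LIMIT = 0.05


@dataclass
class NullModelFit:
    """REML fit of y = 1*mu + g + e on one (LOCO) GRM."""

    sigma2_g: float
    sigma2_e: float
    eigvals: np.ndarray
    eigvecs: np.ndarray
    loglik_reml: float
    chromosome: object = None
    boundary: bool = False  # sigma2_g pinned at (numerically) zero

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


@dataclass
class GwasResult:
    """Per-SNP scan output; untestable SNPs carry NaN and a flag."""

    table: pd.DataFrame  # snp_id, chrom, pos, beta, se, wald, p_value, testable
    n_used: int
    trait: str = "trait"

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p_value"].to_numpy()


def _reml_neg_loglik(log_delta: float, lam: np.ndarray, ty: np.ndarray,
                     t1: np.ndarray) -> float:
    """Negative restricted log-likelihood profiled over sigma2_g.

    delta = sigma2_e / sigma2_g; lam are GRM eigenvalues; ty, t1 the
    rotated response and intercept.
    """
    delta = np.exp(log_delta)
    d = lam + delta
    n = lam.shape[0]
    xdx = np.sum(t1 * t1 / d)
    beta = np.sum(t1 * ty / d) / xdx
    r = ty - t1 * beta
    rss = np.sum(r * r / d)
    sigma2_g = rss / (n - 1)
    # standard form: -0.5[(n-1)log 2pi + log|V| + log|X'V^-1 X| + y'Py]
    ll = -0.5 * (
        (n - 1) * (np.log(2 * np.pi * sigma2_g) + 1)
        + np.sum(np.log(d))
        + np.log(xdx)
    )
    return -ll


def fit_null_reml(y: np.ndarray, grm: GRM | np.ndarray,
                  chromosome=None) -> NullModelFit:
    """REML variance components of the no-SNP model on the GRM eigenbasis."""
    y = np.asarray(y, dtype=float)
    K = grm.matrix if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals for REML")
    if K.shape != (n, n):
        raise ValueError("GRM dimension does not match phenotype length")
    if np.std(y) == 0:
        raise ValueError("constant phenotype; variance components undefined")
    lam, U = np.linalg.eigh((K + K.T) / 2.0)
    neg_mass = -float(lam[lam < 0].sum())
    pos_mass = float(lam[lam > 0].sum())
    if pos_mass == 0 or neg_mass > _NEG_MASS_LIMIT * pos_mass:
        raise ValueError(
            f"GRM is not PSD (min eigenvalue {lam[0]:.3g}, "
            f"negative mass {neg_mass:.3g})"
        )
    lam = np.clip(lam, 0.0, None)
    ty = U.T @ y
    t1 = U.T @ np.ones(n)

    bounds = (-12.0, 12.0)
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=bounds, args=(lam, ty, t1), method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x)
    delta = np.exp(log_delta)
    d = lam + delta
    xdx = np.sum(t1 * t1 / d)
    beta = np.sum(t1 * ty / d) / xdx
    rss = np.sum((ty - t1 * beta) ** 2 / d)
    sigma2_g = rss / (n - 1)
    sigma2_e = sigma2_g * delta
    boundary = log_delta > bounds[1] - 0.5  # huge delta => sigma2_g ~ 0
    if boundary:
        warnings.warn("polygenic variance estimated at the zero boundary")
    return NullModelFit(
        sigma2_g=float(sigma2_g),
        sigma2_e=float(sigma2_e),
        eigvals=lam,
        eigvecs=U,
        loglik_reml=-float(res.fun),
        chromosome=chromosome,
        boundary=boundary,
    )


def fit_loco_nulls(
    geno: GenotypeMatrix, y: np.ndarray, method: str = "gcta_eq2"
) -> dict:
    """One REML null model per chromosome, each on the LOCO GRM."""
    nulls = {}
    for c in geno.chromosomes():
        g = grm_loco(geno, method=method, chromosome_to_exclude=c)
        nulls[c] = fit_null_reml(y, g, chromosome=c)
    return nulls


def _scan_chromosome(
    Xc: np.ndarray, y: np.ndarray, null: NullModelFit,
    sigma2_g_override: float | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GLS of y on [1, x] per SNP under the chromosome's null covariance.

    Returns (beta, se, testable).  The variance ratio is fixed from the
    null fit; the overall scale is re-estimated per SNP from the
    weighted RSS with n-2 degrees of freedom.
    """
    n = y.shape[0]
    sg = null.sigma2_g if sigma2_g_override is None else sigma2_g_override
    if sg == 0.0:
        w = np.ones(n)
        ry, r1, rX = y, np.ones(n), Xc
    else:
        w = 1.0 / (sg * null.eigvals + null.sigma2_e)
        U = null.eigvecs
        ry = U.T @ y
        r1 = U.T @ np.ones(n)
        rX = U.T @ Xc

    a11 = float(np.sum(w * r1 * r1))
    b1 = float(np.sum(w * r1 * ry))
    yy = float(np.sum(w * ry * ry))
    a12 = rX.T @ (w * r1)
    a22 = np.sum(w[:, None] * rX * rX, axis=0)
    b2 = rX.T @ (w * ry)
    det = a11 * a22 - a12**2
    # SNPs (anti)collinear with the intercept have zero weighted partial
    # variance; flag rather than divide by ~0.
    testable = det > 1e-8 * a11 * np.maximum(a22, 1e-300)
    det_safe = np.where(testable, det, 1.0)
    beta = (a11 * b2 - a12 * b1) / det_safe
    mu = (a22 * b1 - a12 * b2) / det_safe
    rss = yy - mu * b1 - beta * b2
    s2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(s2 * a11 / det_safe)
    beta[~testable] = np.nan
    se[~testable] = np.nan
    return beta, se, testable


def wald_scan(
    geno: GenotypeMatrix,
    y: np.ndarray,
    null_fits: dict,
    sigma2_g_override: float | None = None,
    trait: str = "trait",
) -> GwasResult:
    """Chromosome-by-chromosome Wald scan using the matching LOCO null fit.

    ``sigma2_g_override=0`` forces the polygenic term off, reducing each
    test to the OLS Wald statistic.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != geno.n_individuals:
        raise ValueError("phenotype length does not match genotype rows")
    X, _ = imputed_codes(geno)
    beta = np.full(geno.n_snps, np.nan)
    se = np.full(geno.n_snps, np.nan)
    testable = np.zeros(geno.n_snps, dtype=bool)
    for c in geno.chromosomes():
        if c not in null_fits:
            raise ValueError(f"no null model fit for chromosome {c!r}")
        idx = geno.snp_indices_on(c)
        b, s, t = _scan_chromosome(
            X[:, idx], y, null_fits[c], sigma2_g_override
        )
        beta[idx], se[idx], testable[idx] = b, s, t
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = (beta / se) ** 2
        pvals = stats.chi2.sf(wald, df=1)
    table = pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "chrom": geno.chrom,
            "pos": geno.pos,
            "beta": beta,
            "se": se,
            "wald": wald,
            "p_value": pvals,
            "testable": testable,
        }
    )
    return GwasResult(table=table, n_used=y.shape[0], trait=trait)


def wald_scan_exact(
    geno: GenotypeMatrix, y: np.ndarray, null_fits: dict, trait: str = "trait"
) -> GwasResult:
    """Exact variant: re-optimizes the variance ratio for every SNP.

    Orders of magnitude slower than the fixed-ratio scan; intended for
    small data and for quantifying the approximation gap.
    """
    y = np.asarray(y, dtype=float)
    X, _ = imputed_codes(geno)
    n = y.shape[0]
    rows = []
    for c in geno.chromosomes():
        null = null_fits[c]
        lam, U = null.eigvals, null.eigvecs
        ty, t1 = U.T @ y, U.T @ np.ones(n)
        for j in geno.snp_indices_on(c):
            tx = U.T @ X[:, j]
            des = np.column_stack([t1, tx])

            def neg_ll(log_delta):
                d = lam + np.exp(log_delta)
                W = des / d[:, None]
                xtx = des.T @ W
                try:
                    bhat = np.linalg.solve(xtx, W.T @ ty)
                except np.linalg.LinAlgError:
                    return np.inf
                r = ty - des @ bhat
                rss = np.sum(r * r / d)
                s2 = rss / (n - 2)
                sign, logdet_xtx = np.linalg.slogdet(xtx)
                if sign <= 0 or s2 <= 0:
                    return np.inf
                return 0.5 * (
                    (n - 2) * (np.log(2 * np.pi * s2) + 1)
                    + np.sum(np.log(d))
                    + logdet_xtx
                )

            res = optimize.minimize_scalar(
                neg_ll, bounds=(-12, 12), method="bounded",
                options={"xatol": 1e-6},
            )
            d = lam + np.exp(float(res.x))
            W = des / d[:, None]
            xtx = des.T @ W
            try:
                xtx_inv = np.linalg.inv(xtx)
            except np.linalg.LinAlgError:
                rows.append((j, np.nan, np.nan, False))
                continue
            bhat = xtx_inv @ (W.T @ ty)
            r = ty - des @ bhat
            s2 = np.sum(r * r / d) / (n - 2)
            se_j = np.sqrt(s2 * xtx_inv[1, 1])
            rows.append((j, bhat[1], se_j, np.isfinite(se_j) and se_j > 0))
    rows.sort()
    beta = np.array([r[1] for r in rows])
    se = np.array([r[2] for r in rows])
    testable = np.array([r[3] for r in rows])
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = (beta / se) ** 2
        pvals = stats.chi2.sf(wald, df=1)
    table = pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "chrom": geno.chrom,
            "pos": geno.pos,
            "beta": beta,
            "se": se,
            "wald": wald,
            "p_value": pvals,
            "testable": testable,
        }
    )
    return GwasResult(table=table, n_used=n, trait=trait)


def preselect_by_threshold(
    result: GwasResult, threshold: float = 0.05
) -> np.ndarray:
    """Indices of SNPs with p strictly below the threshold, map order kept."""
    p = result.p_values
    selected = np.flatnonzero(p < threshold)
    if selected.size == 0:
        warnings.warn("no SNPs passed the p-value pre-selection threshold")
    return selected
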