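"""GBLUP with one or two genomic relationship matrices.

Model (K relationship matrices, K in {1, 2}):

    y = 1*mu + a_1 + ... + a_K + e,
    a_k ~ N(0, G_k * sigma2_k),   e ~ N(0, D * sigma2_e),

where D is a fixed diagonal of residual weights d_jj = (1 - r2_j)/r2_j
derived from per-individual DRP reliabilities, so low-reliability
records carry proportionally larger residual variance.

Variance components are estimated by restricted maximum likelihood with
average-information (AI) updates; whenever an AI step proposes a
negative component the iteration falls back to the (monotone) EM
update.  GEBVs are the BLUP conditional means
``a_k = sigma2_k * G_k * V^{-1} (y - 1*mu)``, identical to the
mixed-model-equation solutions.  Prediction for unphenotyped
(validation) individuals projects through the cross-block of the GRM:
``a_val = sigma2_k * G[val, ref] * V_ref^{-1} (y_ref - mu)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grm import GRM

__all__ = [
    "ResidualWeights",
    "GblupFit",
    "residual_weights",
    "aireml_fit",
    "predict_gebv",
    "predict_validation",
]

_VAR_FLOOR = 1e-10
_WEIGHT_FLOOR = 1e-6


@dataclass
class ResidualWeights:
    """Diagonal of D; near-noiseless records (r2 = 1) are floored."""

    d: np.ndarray
    floor: float = _WEIGHT_FLOOR
    floored: np.ndarray | None = None  # mask of records hit by the floor

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite residual weights")
        if np.any(self.d < self.floor):
            raise ValueError("weights below the floor; use residual_weights()")


def residual_weights(reliabilities: np.ndarray,
                     floor: float = _WEIGHT_FLOOR) -> ResidualWeights:
    """d_jj = (1 - r2_j) / r2_j, floored at a small positive constant."""
    r2 = np.asarray(reliabilities, dtype=float)
    if np.any(r2 <= 0) or np.any(r2 > 1):
        raise ValueError("reliabilities must lie in (0, 1]")
    d = (1.0 - r2) / r2
    floored = d < floor
    if floored.any():
        warnings.warn(
            f"{int(floored.sum())} records have reliability ~1; residual "
            "weight floored (near-noiseless observations)"
        )
        d = np.maximum(d, floor)
    return ResidualWeights(d=d, floor=floor, floored=floored)


@dataclass
class GblupFit:
    """Converged (or capped) REML fit plus BLUP solutions."""

    mu: float
    gebv: np.ndarray  # total genomic value per individual
    gebv_components: list  # per-GRM split; sums to gebv
    variance_components: np.ndarray  # per-GRM sigma2_k
    sigma2_e: float
    residuals: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    loglik_path: np.ndarray = field(repr=False, default=None)

    @property
    def h2(self) -> float:
        tot = float(self.variance_components.sum() + self.sigma2_e)
        return float(self.variance_components.sum()) / tot if tot > 0 else 0.0


def _as_matrix(g) -> np.ndarray:
    return g.matrix if isinstance(g, GRM) else np.asarray(g, dtype=float)


def _check_psd(K: np.ndarray, label: str) -> None:
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError(f"{label} is not symmetric")
    w = np.linalg.eigvalsh(K)
    if w[0] < -1e-6:
        raise ValueError(f"{label} is not PSD (min eigenvalue {w[0]:.3g})")


def _reml_pieces(y, X, Vmats, theta):
    """V, P y, P, REML loglik at the current components."""
    n = y.shape[0]
    V = sum(t * M for t, M in zip(theta, Vmats))
    try:
        c = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"V not positive definite at theta={theta}"
        ) from exc
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    cond = np.linalg.cond(XtViX)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular fixed-effect coefficient matrix (cond={cond:.3g})"
        )
    ViX = Vi @ X
    P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
    Py = P @ y
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    sign, logdet_X = np.linalg.slogdet(XtViX)
    ll = -0.5 * (logdet_V + logdet_X + float(y @ Py)
                 + (n - X.shape[1]) * np.log(2 * np.pi))
    return V, Vi, P, Py, ll


def aireml_fit(
    y: np.ndarray,
    grms,
    weights: ResidualWeights | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
    init: np.ndarray | None = None,
    algorithm: str = "ai",
) -> GblupFit:
    """AI-REML variance components and BLUP solutions.

    Parameters
    ----------
    y : response (DRPs of the phenotyped individuals)
    grms : one GRM/array or a sequence of them (random-effect covariances)
    weights : residual weights D; identity when None
    algorithm : "ai" (average information with EM fallback) or "em"

    Non-convergence at ``max_iter`` is reported via ``converged=False``,
    never raised.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if isinstance(grms, (GRM, np.ndarray)):
        grms = [grms]
    Gs = [_as_matrix(g) for g in grms]
    for i, K in enumerate(Gs):
        if K.shape != (n, n):
            raise ValueError(f"GRM {i} dimension {K.shape} != n={n}")
        _check_psd(K, f"GRM {i}")
    D = np.diag(weights.d) if weights is not None else np.eye(n)
    Vmats = Gs + [D]
    K = len(Vmats)
    X = np.ones((n, 1))

    vy = y.var(ddof=1)
    if vy == 0:
        raise ValueError("constant response")
    theta = (np.full(K, vy / K) if init is None
             else np.asarray(init, dtype=float).copy())

    ll_path = []
    converged = False
    it = 0
    V = Vi = P = Py = None
    ll = -np.inf
    for it in range(1, max_iter + 1):
        V, Vi, P, Py, ll = _reml_pieces(y, X, Vmats, theta)
        ll_path.append(ll)
        t_vecs = [M @ Py for M in Vmats]
        score = np.array([
            -0.5 * (np.sum(P * M) - float(Py @ M @ Py)) for M in Vmats
        ])
        use_em = algorithm == "em"
        proposal = None
        if not use_em:
            AI = 0.5 * np.array(
                [[float(t_vecs[i] @ P @ t_vecs[j]) for j in range(K)]
                 for i in range(K)]
            )
            try:
                step = np.linalg.solve(AI, score)
                proposal = theta + step
            except np.linalg.LinAlgError:
                use_em = True
            if proposal is not None and np.any(proposal < _VAR_FLOOR):
                use_em = True
        if use_em:
            # EM update: monotone in the restricted likelihood, stays >= 0
            proposal = np.array([
                theta[i] + theta[i] ** 2
                * (float(Py @ Vmats[i] @ Py) - np.sum(P * Vmats[i])) / n
                for i in range(K)
            ])
        proposal = np.maximum(proposal, _VAR_FLOOR)
        delta = np.linalg.norm(proposal - theta) / max(1.0, np.linalg.norm(theta))
        theta = proposal
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"AI-REML did not converge in {max_iter} iterations")

    V, Vi, P, Py, ll = _reml_pieces(y, X, Vmats, theta)
    XtViX = (X.T @ Vi @ X).item()
    mu = (X.T @ Vi @ y).item() / XtViX
    resid_rot = Vi @ (y - mu)
    comps = [theta[i] * Gs[i] @ resid_rot for i in range(len(Gs))]
    gebv = np.sum(comps, axis=0)
    return GblupFit(
        mu=mu,
        gebv=gebv,
        gebv_components=comps,
        variance_components=theta[: len(Gs)].copy(),
        sigma2_e=float(theta[-1]),
        residuals=y - mu - gebv,
        converged=converged,
        n_iter=it,
        loglik=ll,
        loglik_path=np.asarray(ll_path),
    )


def predict_gebv(
    y: np.ndarray,
    grms,
    variance_components: np.ndarray,
    sigma2_e: float,
    weights: ResidualWeights | None = None,
    mu: float | None = None,
) -> tuple[float, np.ndarray, list]:
    """BLUP conditional means at fixed variance components.

    Returns (mu, total gebv, per-component gebv).  With mu=None the GLS
    mean is computed under the same covariance.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if isinstance(grms, (GRM, np.ndarray)):
        grms = [grms]
    Gs = [_as_matrix(g) for g in grms]
    vc = np.asarray(variance_components, dtype=float)
    D = np.diag(weights.d) if weights is not None else np.eye(n)
    V = sum(v * G for v, G in zip(vc, Gs)) + sigma2_e * D
    Vi_y = np.linalg.solve(V, y)
    ones = np.ones(n)
    Vi_1 = np.linalg.solve(V, ones)
    if mu is None:
        mu = float(ones @ Vi_y) / float(ones @ Vi_1)
    r = np.linalg.solve(V, y - mu * ones)
    comps = [v * G @ r for v, G in zip(vc, Gs)]
    total = np.sum(comps, axis=0)
    if not np.all(np.isfinite(total)):
        raise ValueError("non-finite GEBV")
    return float(mu), total, comps


def predict_validation(
    fit: GblupFit,
    grms,
    y_ref: np.ndarray,
    ref_idx: np.ndarray,
    val_idx: np.ndarray,
    weights_ref: ResidualWeights | None = None,
) -> np.ndarray:
    """GEBVs for unphenotyped individuals by GRM cross-block projection.

    ``grms`` are full-population matrices (reference + validation rows);
    the fit's variance components and mean come from the reference-only
    REML.
    """
    if isinstance(grms, (GRM, np.ndarray)):
        grms = [grms]
    Gs = [_as_matrix(g) for g in grms]
    ref_idx = np.asarray(ref_idx)
    val_idx = np.asarray(val_idx)
    n_ref = ref_idx.size
    D = np.diag(weights_ref.d) if weights_ref is not None else np.eye(n_ref)
    V_ref = sum(
        v * G[np.ix_(ref_idx, ref_idx)]
        for v, G in zip(fit.variance_components, Gs)
    ) + fit.sigma2_e * D
    r = np.linalg.solve(V_ref, np.asarray(y_ref, dtype=float) - fit.mu)
    gebv_val = np.zeros(val_idx.size)
    for v, G in zip(fit.variance_components, Gs):
        gebv_val += v * G[np.ix_(val_idx, ref_idx)] @ r
    if not np.all(np.isfinite(gebv_val)):
        raise ValueError("non-finite validation GEBV")
    return gebv_val
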