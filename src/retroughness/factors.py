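"""Dimensionality structure of layer roughness.

Principal-component variance shares, maximum-likelihood exploratory factor
analysis with varimax rotation, the chi-square test that k factors are
sufficient, and the sampling-adequacy diagnostics (Kaiser-Meyer-Olkin
index, Bartlett's sphericity test, determinant of the correlation matrix).

The ML extraction profiles out the loadings: for uniquenesses Psi the
discrepancy is F(Psi) = sum_{j>k} (lambda_j - ln lambda_j - 1) over the
trailing eigenvalues of Psi^{-1/2} R Psi^{-1/2}; Psi is optimised
numerically and the loadings recovered from the leading eigenvectors.
The sufficiency statistic uses Bartlett's correction,
chi2 = (n - 1 - (2p + 5)/6 - 2k/3) * F_min with df = ((p - k)^2 - p - k)/2,
matching the classic likelihood-ratio test.  Factor order is arbitrary;
columns are sign-aligned so each factor's largest-magnitude loading is
positive, and factors are matched to variable blocks by dominant loadings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .stats import TestResult

_PSI_FLOOR = 0.005


def _check_corr(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    return corr


def pca_explained(corr: np.ndarray) -> np.ndarray:
    """Per-component variance proportions (descending eigenvalues / p)."""
    corr = _check_corr(corr)
    eigvals = np.linalg.eigvalsh(corr)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    return eigvals / corr.shape[0]


def corr_determinant(corr: np.ndarray) -> float:
    """Determinant of the correlation matrix (0 when singular)."""
    corr = _check_corr(corr)
    return float(max(0.0, np.linalg.det(corr)))


def bartlett_sphericity(corr: np.ndarray, n: int) -> TestResult:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R), df = p (p - 1) / 2.
    """
    corr = _check_corr(corr)
    p = corr.shape[0]
    det = np.linalg.det(corr)
    if det <= 0:
        raise ValueError("singular correlation matrix")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * np.log(det)
    df = p * (p - 1) // 2
    return TestResult(
        name="Bartlett sphericity", statistic=float(chi2),
        p_value=float(sps.chi2(df).sf(chi2)), df=df,
    )


def kmo_index(corr: np.ndarray) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over off-diagonal cells,
    with q the anti-image (partial) correlations obtained from the inverse
    correlation matrix.
    """
    corr = _check_corr(corr)
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular correlation matrix; KMO undefined") from e
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(corr.shape[0], dtype=bool)
    r2 = (corr[off] ** 2).sum()
    q2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + q2))


def sufficiency_df(p: int, k: int) -> int:
    """Degrees of freedom of the k-factor sufficiency test: ((p-k)^2 - p - k)/2."""
    return ((p - k) ** 2 - p - k) // 2


def _ml_objective(log_psi: np.ndarray, corr: np.ndarray, k: int) -> float:
    psi = np.exp(log_psi)
    scale = 1.0 / np.sqrt(psi)
    sstar = corr * np.outer(scale, scale)
    eig = np.linalg.eigvalsh(sstar)[::-1]
    tail = np.clip(eig[k:], 1e-12, None)
    return float(np.sum(tail - np.log(tail) - 1.0))


def _ml_loadings(psi: np.ndarray, corr: np.ndarray, k: int) -> np.ndarray:
    scale = 1.0 / np.sqrt(psi)
    sstar = corr * np.outer(scale, scale)
    eigval, eigvec = np.linalg.eigh(sstar)
    order = np.argsort(eigval)[::-1][:k]
    lam = np.clip(eigval[order] - 1.0, 0.0, None)
    load_star = eigvec[:, order] * np.sqrt(lam)
    return load_star * np.sqrt(psi)[:, None]


def varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Varimax orthogonal rotation (SVD form of the pairwise criterion)."""
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    R = np.eye(k)
    last = 0.0
    for _ in range(max_iter):
        rotated = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (rotated**3 - rotated @ np.diag((rotated**2).sum(axis=0)) / p)
        )
        R = u @ vt
        crit = s.sum()
        if crit - last < tol * max(crit, 1.0):
            break
        last = crit
    return L @ R


def _sign_align(loadings: np.ndarray) -> np.ndarray:
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))


@dataclass
class FactorModel:
    """Fitted orthogonal factor model on a correlation matrix."""

    loadings: pd.DataFrame
    uniquenesses: np.ndarray
    variance_explained: np.ndarray
    chi2_sufficiency: TestResult
    kmo: float
    bartlett: TestResult
    corr_det: float
    n_obs: int
    converged: bool
    heywood: bool

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]


def fit_factor_model_corr(
    corr: np.ndarray,
    n_obs: int,
    n_factors: int = 2,
    var_names: list[str] | None = None,
    rotate: bool = True,
) -> FactorModel:
    """ML factor extraction from a correlation matrix with varimax rotation."""
    corr = _check_corr(corr)
    p = corr.shape[0]
    k = n_factors
    if sufficiency_df(p, k) < 0:
        raise ValueError(f"{k} factors over-parameterise {p} variables")
    inv_diag = np.diag(np.linalg.inv(corr))
    psi0 = np.clip((1.0 - 0.5 * k / p) / inv_diag, _PSI_FLOOR, 1.0)
    res = optimize.minimize(
        _ml_objective,
        np.log(psi0),
        args=(corr, k),
        method="L-BFGS-B",
        bounds=[(np.log(_PSI_FLOOR), 0.0)] * p,
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-10},
    )
    if not res.success and res.fun > _ml_objective(np.log(psi0), corr, k):
        raise RuntimeError(f"ML factor extraction failed to converge: {res.message}")
    psi = np.exp(res.x)
    heywood = bool((psi <= _PSI_FLOOR * (1 + 1e-6)).any())
    loadings = _ml_loadings(psi, corr, k)
    if rotate and k > 1:
        loadings = varimax(loadings)
    loadings = _sign_align(loadings)

    fmin = float(res.fun)
    df = sufficiency_df(p, k)
    chi2 = max(0.0, (n_obs - 1 - (2 * p + 5) / 6.0 - 2 * k / 3.0) * fmin)
    chi2_test = TestResult(
        name="factor sufficiency",
        statistic=chi2,
        p_value=float(sps.chi2(df).sf(chi2)) if df > 0 else np.nan,
        df=df,
    )
    var_names = var_names or [f"v{i + 1}" for i in range(p)]
    load_df = pd.DataFrame(
        loadings, index=var_names, columns=[f"factor_{j + 1}" for j in range(k)]
    )
    return FactorModel(
        loadings=load_df,
        uniquenesses=psi,
        variance_explained=(loadings**2).sum(axis=0) / p,
        chi2_sufficiency=chi2_test,
        kmo=kmo_index(corr),
        bartlett=bartlett_sphericity(corr, n_obs),
        corr_det=corr_determinant(corr),
        n_obs=n_obs,
        converged=bool(res.success),
        heywood=heywood,
    )


def fit_two_factor(
    data: pd.DataFrame,
    n_factors: int = 2,
    include_covariates: bool = False,
) -> FactorModel:
    """Two-factor model of the 10 layer FDs (optionally + MMSE, VA, age).

    ``data`` is a cohort table; rows with missing values are dropped.
    """
    cols = [c for c in data.columns if c.startswith("fd_layer_")]
    if include_covariates:
        cols += [c for c in ("mmse", "visual_acuity", "age") if c in data.columns]
    sub = data[cols].dropna()
    if len(sub) < 15:
        raise ValueError("need at least 15 complete rows for factor analysis")
    corr = np.corrcoef(sub.to_numpy(), rowvar=False)
    return fit_factor_model_corr(
        corr, n_obs=len(sub), n_factors=n_factors, var_names=cols
    )


def dominant_factor(model: FactorModel) -> pd.Series:
    """Factor index (1-based) with the largest absolute loading per variable."""
    return pd.Series(
        model.loadings.abs().to_numpy().argmax(axis=1) + 1,
        index=model.loadings.index,
    )
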