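"""Maximum-likelihood single-factor model for standardized scores.

Fits the covariance-structure model

    Sigma(lambda, theta) = lambda lambda' + diag(theta),

with the factor variance fixed at 1, by minimizing the normal-theory ML
discrepancy

    F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

over the loadings lambda and residual variances theta.  chi2 = n * F at the
optimum; the independence baseline (diagonal Sigma) feeds the NFI/CFI
incremental fit indices, and RMSEA is computed from the model chi2.

Per-person quantities follow: regression-method factor scores
f_i = lambda' Sigma^-1 x_i, predicted manifest values x_hat_ij =
lambda_j f_i, and the within-individual residual variance
rv_i = mean_j (x_ij - x_hat_ij)^2 with its natural log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .matrix import ScoreMatrix

__all__ = [
    "FactorSolution",
    "fit_single_factor",
    "factor_scores",
    "predicted_and_residuals",
    "fit_indices",
]

log = logging.getLogger(__name__)

THETA_FLOOR = 1e-4      # residual variances pinned here mark a Heywood case
RESID_VAR_FLOOR = 1e-12  # keeps log residual variance finite


@dataclass(frozen=True)
class FactorSolution:
    """Parameters and fit statistics of one single-factor ML solution."""

    loadings: np.ndarray
    residual_variances: np.ndarray
    converged: bool
    heywood: bool
    n: int
    chi2: float
    df: int
    baseline_chi2: float
    baseline_df: int
    nfi: float
    cfi: float
    rmsea: float
    discrepancy: float
    just_identified: bool = False

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    @property
    def weak(self) -> bool:
        """True when no measure loads meaningfully on the factor."""
        return bool(np.max(np.abs(self.loadings)) < 0.1)

    @property
    def implied_cov(self) -> np.ndarray:
        lam, theta = self.loadings, self.residual_variances
        return np.outer(lam, lam) + np.diag(theta)


def _discrepancy(params: np.ndarray, S: np.ndarray, logdet_S: float, p: int):
    """ML discrepancy and its gradient in (lambda, ln theta) coordinates."""
    lam = params[:p]
    theta = np.exp(params[p:])
    sigma = np.outer(lam, lam) + np.diag(theta)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(params)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    sigma_inv = np.linalg.inv(sigma)
    F = logdet + float(np.sum(sigma_inv * S)) - logdet_S - p
    # dF/dSigma = Sigma^-1 (Sigma - S) Sigma^-1
    A = sigma_inv @ (sigma - S) @ sigma_inv
    grad = np.concatenate([2.0 * A @ lam, np.diag(A) * theta])
    return F, grad


def _fit_cov(S: np.ndarray, n: int, n_restarts: int = 3, seed: int = 0):
    """Minimize the discrepancy from a PCA start plus random restarts."""
    p = S.shape[0]
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular sample covariance")
    evals, evecs = np.linalg.eigh(S)
    v, e = evecs[:, -1], evals[-1]
    lam0 = v * np.sqrt(max(e - 1.0, 0.5 * e))
    theta0 = np.clip(np.diag(S) - lam0**2, 0.05, None)
    rng = np.random.default_rng(seed)
    starts = [(lam0, theta0)]
    for _ in range(n_restarts):
        jitter = rng.normal(scale=0.1, size=p)
        starts.append((lam0 + jitter, np.clip(theta0 * rng.uniform(0.5, 1.5, p), 0.05, None)))

    bounds = [(None, None)] * p + [(np.log(THETA_FLOOR), 20.0)] * p
    best = None
    for lam_s, theta_s in starts:
        x0 = np.concatenate([lam_s, np.log(theta_s)])
        res = optimize.minimize(
            _discrepancy,
            x0,
            args=(S, logdet_S, p),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    lam = best.x[:p]
    theta = np.exp(best.x[p:])
    # no-common-variance data: the zero-loading model fits just as well, and
    # any single-spike solution is an unidentified tie -- report lam = 0
    F_null = float(np.sum(np.log(np.diag(S))) - logdet_S)
    if best.fun >= F_null - 1e-9:
        lam = np.zeros(p)
        theta = np.diag(S).copy()
        return lam, theta, F_null, True, False
    if lam.sum() < 0:   # sign convention: higher latent score = better
        lam = -lam
    heywood = bool(np.any(theta <= THETA_FLOOR * 1.01))
    converged = bool(best.success) and not heywood
    return lam, theta, float(best.fun), converged, heywood


def fit_indices(
    chi2: float, df: int, baseline_chi2: float, baseline_df: int, n: int
) -> tuple[float, float, float]:
    """NFI, CFI and RMSEA from the model and independence-baseline chi2.

    RMSEA = sqrt(max(chi2 - df, 0) / (df * n)); a just-identified model
    (df = 0) reports RMSEA 0.
    """
    nfi = (baseline_chi2 - chi2) / baseline_chi2 if baseline_chi2 > 0 else float("nan")
    num = max(chi2 - df, 0.0)
    den = max(baseline_chi2 - baseline_df, chi2 - df, 0.0)
    cfi = 1.0 - num / den if den > 0 else 1.0
    rmsea = np.sqrt(max(chi2 - df, 0.0) / (df * n)) if df > 0 else 0.0
    return float(nfi), float(cfi), float(rmsea)


def fit_single_factor(
    m: ScoreMatrix, n_restarts: int = 3, seed: int = 0
) -> FactorSolution:
    """Fit the single-factor model to a standardized score matrix.

    Requires the standardized flag and n >= p + 5.  The reported chi2 is
    n * F with S the ML (denominator n) sample covariance.  A residual
    variance pinned at its lower bound flags a Heywood case and marks the
    solution non-converged rather than hiding it.
    """
    if not m.standardized:
        raise ValueError("fit_single_factor expects a standardized ScoreMatrix")
    return fit_single_factor_cov(
        np.cov(m.values, rowvar=False, ddof=0), m.n_persons, n_restarts, seed
    )


def fit_single_factor_cov(
    S: np.ndarray, n: int, n_restarts: int = 3, seed: int = 0
) -> FactorSolution:
    """Fit from an explicit covariance matrix (denominator n) and size n."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if n < p + 5:
        raise ValueError(f"sample too small to fit: n={n} < p+5={p + 5}")
    lam, theta, F, converged, heywood = _fit_cov(S, n, n_restarts, seed)
    if heywood:
        log.info("Heywood case: residual variance at lower bound")

    df = p * (p + 1) // 2 - 2 * p
    chi2 = n * F
    # independence baseline: Sigma_b = diag(S); tr(S Sigma_b^-1) = p exactly
    sign, logdet_S = np.linalg.slogdet(S)
    F_b = float(np.sum(np.log(np.diag(S))) - logdet_S)
    baseline_chi2 = n * F_b
    baseline_df = p * (p - 1) // 2
    nfi, cfi, rmsea = fit_indices(chi2, df, baseline_chi2, baseline_df, n)
    return FactorSolution(
        loadings=lam,
        residual_variances=theta,
        converged=converged,
        heywood=heywood,
        n=n,
        chi2=float(chi2),
        df=df,
        baseline_chi2=float(baseline_chi2),
        baseline_df=baseline_df,
        nfi=nfi,
        cfi=cfi,
        rmsea=rmsea,
        discrepancy=F,
        just_identified=(df == 0),
    )


def _as_values_index(m) -> tuple[np.ndarray, pd.Index]:
    if isinstance(m, ScoreMatrix):
        return m.values, m.person_ids
    frame = pd.DataFrame(m)
    return frame.to_numpy(dtype=float), frame.index


def factor_scores(sol: FactorSolution, m) -> pd.Series:
    """Regression-method latent scores f_i = lambda' Sigma_hat^-1 x_i.

    Uses the model-implied covariance, matching the default score estimator
    for continuous indicators in standard SEM software.  Accepts a
    ScoreMatrix or any person x measure DataFrame/array.
    """
    vals, index = _as_values_index(m)
    sigma_inv = np.linalg.inv(sol.implied_cov)
    weights = sigma_inv @ sol.loadings
    return pd.Series(vals @ weights, index=index, name="fscore")


def predicted_and_residuals(
    sol: FactorSolution, fscores: pd.Series, m
) -> pd.DataFrame:
    """Per-person predicted values, residual variance and its log.

    x_hat_ij = lambda_j * f_i; resid_var_i = mean_j (x_ij - x_hat_ij)^2.
    A zero residual variance is floored at a machine-safe epsilon (logged)
    so the log stays finite.
    """
    vals, index = _as_values_index(m)
    xhat = np.outer(fscores.to_numpy(), sol.loadings)
    resid = vals - xhat
    rv = (resid**2).mean(axis=1)
    floored = rv < RESID_VAR_FLOOR
    if floored.any():
        log.info("predicted_and_residuals: floored %d residual variances", floored.sum())
        rv = np.maximum(rv, RESID_VAR_FLOOR)
    return pd.DataFrame(
        {
            "fscore": fscores.to_numpy(),
            "resid_var": rv,
            "log_resid_var": np.log(rv),
        },
        index=index,
    )
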