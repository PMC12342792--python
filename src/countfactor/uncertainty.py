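"""Fisher-information standard errors for factor scores and loadings.

For cell j the M x M diagonal block of the Fisher information for its score
vector v_j is

    F_j = (U Sigma)^T diag(mu_1j, ..., mu_Ij) (U Sigma)

(the negative expected Hessian of the Poisson log-likelihood in v_j).
Plugging in the fitted parameters and taking sqrt(diag(F_j^{-1})) gives
approximate standard errors.  Because the other parameters (alpha, beta, U,
Sigma) are treated as fixed, these are *underestimates* of the true
uncertainty; empirically the resulting normal intervals are only slightly
anti-conservative for large I and J.  Loading standard errors use the same
computation transposed: G_i = (V Sigma)^T diag(mu_i.) (V Sigma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .model_core import GBMFit, mean_matrix


@dataclass
class ScoreSE:
    """Raw (level-free) standard errors: se_V is J x M, se_U optionally I x M."""

    se_V: np.ndarray
    se_U: np.ndarray | None = None


def fisher_block(U: np.ndarray, sigma: np.ndarray, mu_col: np.ndarray) -> np.ndarray:
    """Fisher information block F_j = (U Sigma)^T diag(mu_col) (U Sigma)."""
    U = np.asarray(U, dtype=float)
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    mu_col = np.asarray(mu_col, dtype=float).ravel()
    if U.ndim != 2 or U.shape[0] != mu_col.shape[0] or U.shape[1] != len(sigma):
        raise ValueError(
            f"shape mismatch: U {U.shape}, sigma {sigma.shape}, mu {mu_col.shape}"
        )
    B = U * sigma
    return B.T @ (mu_col[:, None] * B)


def _block_ses(B: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """sqrt(diag(F^{-1})) for every column of mu; F = B^T diag(mu_col) B."""
    J = mu.shape[1]
    M = B.shape[1]
    F = np.einsum("im,ij,in->jmn", B, mu, B, optimize=True)
    se = np.empty((J, M))
    try:
        inv = np.linalg.inv(F)
        diag = np.einsum("jmm->jm", inv)
        bad = np.any(diag <= 0, axis=1)
    except np.linalg.LinAlgError:
        diag = np.full((J, M), -1.0)
        bad = np.ones(J, dtype=bool)
    se[~bad] = np.sqrt(diag[~bad])
    if np.any(bad):
        warnings.warn(
            f"singular Fisher block for {int(bad.sum())} cell(s); "
            "pseudo-inverse standard errors flagged",
            RuntimeWarning,
        )
        for j in np.flatnonzero(bad):
            pinv = np.linalg.pinv(F[j])
            se[j] = np.sqrt(np.abs(np.diag(pinv)))
    return se


def score_standard_errors(fit: GBMFit, compute_loadings: bool = False) -> ScoreSE:
    """Per-entry standard errors for V (and optionally U) at the fitted means."""
    mu = mean_matrix(fit)
    B = fit.U * fit.sigma
    se_V = _block_ses(B, mu)
    se_U = None
    if compute_loadings:
        se_U = _block_ses(fit.V * fit.sigma, mu.T)
    return ScoreSE(se_V=se_V, se_U=se_U)


def confidence_intervals(fit: GBMFit, se: ScoreSE, level: float = 0.95):
    """Normal-theory intervals v_hat_jm +/- z_{(1+level)/2} * se_jm.

    Returns (lower, upper) arrays of shape J x M.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = norm.ppf(0.5 * (1 + level))
    lower = fit.V - z * se.se_V
    upper = fit.V + z * se.se_V
    return lower, upper
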