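"""Iteratively reweighted SVD (IRSVD) fitting of the Poisson bilinear model.

Each outer iteration alternates two closed-form steps:

1. *Working update of X*: a second-order Taylor expansion of the Poisson
   log-posterior at the current estimates turns the problem into a weighted
   low-rank regression with weights ``W_ij = mu_ij / mu_*`` (``mu_*`` the
   largest fitted mean) and working response
   ``Z_ij = X_ij + (Y_ij - mu_ij)/mu_ij``.  One soft-impute step solves it:

       X  <-  SVD_{M,tau}( X + W o (Z - X) )  =  SVD_{M,tau}( X + (Y - mu)/mu_* )

   where ``SVD_{M,tau}`` is the rank-M truncated SVD with singular values
   soft-thresholded by tau.  The simplified argument on the right is used
   directly, so only one dense I x J working array is formed.

2. *Intercept update*: with X fixed the Poisson MLEs of all gene intercepts
   (then all cell intercepts) have closed forms and are updated
   simultaneously; each sweep cannot decrease the likelihood.

The Taylor surrogate does not guarantee ascent, so the X step is damped:
if the penalized objective drops, the new X is pulled back toward the old
one (convex combination, re-truncated) up to 5 halvings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse.linalg as spla
from scipy.special import logsumexp

from .model_core import (
    DEFAULT_CAP,
    CountMatrix,
    OverflowCapError,
    GBMFit,
    as_count_matrix,
    canonicalize,
    check_margins,
    fix_signs,
    log_posterior,
    mean_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class IRSVDConfig:
    """Settings for :func:`fit_gbm`.

    M : number of latent factors (0 gives the two-way intercept model).
    tau : rate of the Exponential prior on sigma; the soft-threshold amount.
        Default 0 (unpenalized MLE).
    max_iter, tol : outer-loop stopping rule on the relative change of the
        penalized log-posterior.
    seed : controls the deterministic start vector of the truncated SVD.
    cap : linear-predictor cap (natural log scale) guarding exp overflow.
    center_factors : absorb row/column means of X into the intercepts in the
        final canonicalization.
    """

    M: int = 10
    tau: float = 0.0
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    cap: float = DEFAULT_CAP
    center_factors: bool = True

    def __post_init__(self) -> None:
        if self.M < 0:
            raise ValueError("M must be >= 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


def initialize(Y, cfg: IRSVDConfig) -> GBMFit:
    """Closed-form intercept start with X = 0.

    ``beta_j = log S_j - mean(log S)`` (centered log depth) and
    ``alpha_i = log(row sum) - log(sum_j exp(beta_j))``, which makes the
    initial means exactly (row sum)(column sum)/total — the two-way Poisson
    intercept model, i.e. the base model of analytic Pearson residuals.
    """
    Y = as_count_matrix(Y)
    check_margins(Y)
    if cfg.M > min(Y.shape):
        raise ValueError(f"M={cfg.M} exceeds min(I, J)={min(Y.shape)}")
    S = Y.cell_sums().astype(float)
    beta = np.log(S) - np.mean(np.log(S))
    alpha = np.log(Y.gene_sums().astype(float)) - logsumexp(beta)
    I, J = Y.shape
    return GBMFit(
        alpha, beta,
        np.zeros((I, 0)), np.zeros(0), np.zeros((J, 0)),
        tau=cfg.tau,
    )


def _truncated_svd(A: np.ndarray, k: int, seed: int = 0):
    """Top-k SVD, descending; exact for small matrices, ARPACK otherwise."""
    n = min(A.shape)
    if k >= n or n <= 200 or k > n // 5:
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
        return U[:, :k], s[:k], Vt[:k].T
    v0 = np.random.default_rng(seed).standard_normal(n)
    U, s, Vt = spla.svds(A, k=k, v0=v0)
    order = np.argsort(s)[::-1]
    return U[:, order], s[order], Vt[order].T


def svd_soft_threshold(A: np.ndarray, M: int, tau: float, seed: int = 0):
    """Rank-M truncated SVD with singular values soft-thresholded by tau.

    Returns (U, sigma, V) in canonical form; components whose thresholded
    singular value is zero are dropped.
    """
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix passed to svd_soft_threshold has non-finite entries")
    k = min(M, min(A.shape))
    if k == 0:
        return np.zeros((A.shape[0], 0)), np.zeros(0), np.zeros((A.shape[1], 0))
    U, s, V = _truncated_svd(A, k, seed=seed)
    s = s - tau
    keep = s > 0
    U, s, V = U[:, keep], s[keep], V[:, keep]
    U, V = fix_signs(U, V)
    return U, s, V


def working_update(Y, fit: GBMFit, cfg: IRSVDConfig, step: float = 1.0) -> GBMFit:
    """One soft-impute step on X at fixed intercepts.

    Uses the identity W o (Z - X) = (Y - mu)/mu_* so only a single dense
    I x J working array is materialized.  ``step`` rescales the gradient
    term (step=1 is the plain majorization step 1/mu_*); :func:`fit_gbm`
    adapts it with backtracking, which changes neither the update direction
    nor the fixed points.
    """
    Y = as_count_matrix(Y)
    mu = mean_matrix(fit, cap=cfg.cap)
    mu_star = float(mu.max())
    if mu_star <= 0:
        raise RuntimeError("max fitted mean is zero; invalid state")
    A = Y.dense()  # the single dense working array
    A -= mu
    A *= step / mu_star
    A += fit.interaction()
    U, s, V = svd_soft_threshold(A, cfg.M, cfg.tau, seed=cfg.seed)
    return replace(fit, U=U, sigma=s, V=V)


def update_intercepts(Y, fit: GBMFit, cap: float = DEFAULT_CAP) -> GBMFit:
    """Closed-form simultaneous MLE sweep of alpha then beta at fixed X."""
    Y = as_count_matrix(Y)
    check_margins(Y)
    X = fit.interaction()
    gs = Y.gene_sums().astype(float)
    cs = Y.cell_sums().astype(float)
    alpha = np.log(gs) - logsumexp(fit.beta[None, :] + X, axis=1)
    beta = np.log(cs) - logsumexp(alpha[:, None] + X, axis=0)
    return replace(fit, alpha=alpha, beta=beta)


def fit_gbm(Y, cfg: IRSVDConfig | None = None, **cfg_kwargs) -> GBMFit:
    """Fit the Poisson bilinear model by IRSVD.

    Alternates :func:`working_update` and :func:`update_intercepts` from the
    closed-form start until the relative change of the penalized
    log-posterior falls below ``cfg.tol`` or ``cfg.max_iter`` is reached.
    Deterministic given (Y, cfg).  On non-convergence the best iterate is
    returned with ``converged=False`` and a warning.
    """
    if cfg is None:
        cfg = IRSVDConfig(**cfg_kwargs)
    Y = as_count_matrix(Y)
    fit = initialize(Y, cfg)
    obj = log_posterior(Y, fit, cap=cfg.cap)
    trace = [obj]
    best_fit, best_obj = fit, obj
    converged = False
    step = 1.0
    for _ in range(cfg.max_iter):
        if cfg.M > 0:
            fit, step = _adaptive_x_step(Y, fit, cfg, obj, step)
        fit = update_intercepts(Y, fit, cap=cfg.cap)
        new_obj = log_posterior(Y, fit, cap=cfg.cap)
        trace.append(new_obj)
        if new_obj >= best_obj:
            best_fit, best_obj = fit, new_obj
        if abs(new_obj - obj) / (abs(obj) + 1.0) < cfg.tol:
            converged = True
            obj = new_obj
            break
        obj = new_obj
    if not converged:
        warnings.warn(
            f"IRSVD did not converge in {cfg.max_iter} iterations; "
            "returning best iterate",
            RuntimeWarning,
        )
        fit = best_fit
    out = canonicalize(
        fit.alpha, fit.beta, fit.U, fit.sigma, fit.V,
        tau=cfg.tau, center_factors=cfg.center_factors,
    )
    out.trace = trace
    out.converged = converged
    out.meta = {
        "variant": "full", "M": cfg.M, "tau": cfg.tau,
        "tol": cfg.tol, "seed": cfg.seed, "n_iter": len(trace) - 1,
    }
    return out


def _adaptive_x_step(Y: CountMatrix, fit: GBMFit, cfg: IRSVDConfig,
                     prev_obj: float, step: float) -> tuple[GBMFit, float]:
    """Working update with backtracking step control.

    The plain step (step=1) is the global majorization bound 1/mu_*, which
    is far too conservative when the fitted means are heterogeneous.  The
    step is grown geometrically across iterations while the objective keeps
    improving and halved (up to 8 times within an iteration, guarding
    against exp overflow) when it would decrease by more than 1e-8 — a
    monotone safeguard around the same update direction and fixed points.
    """
    for _ in range(8):
        try:
            cand = working_update(Y, fit, cfg, step=step)
            cand_obj = log_posterior(Y, cand, cap=cfg.cap)
        except OverflowCapError:
            step *= 0.5
            continue
        if cand_obj >= prev_obj - 1e-8:
            return cand, min(step * 2.0, 1e6)
        step *= 0.5
    logger.debug("adaptive X step found no improving step; keeping old X")
    return fit, max(step, 1.0)
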