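"""Subsample-and-project fitting for large numbers of cells.

The IRSVD fit scales linearly in the number of cells J.  For very large J
the gene-side parameters (alpha, U, Sigma) are estimated on a random cell
subset, then frozen; each cell's (beta_j, v_j) is recovered independently by
a Poisson GLM regression of its count column on the design [1, U] with
offset alpha, since at fixed U the model for one column is an ordinary GLM
with coefficients (beta_j, sigma_1 v_j1, ..., sigma_M v_jM).  Columns are
processed one at a time, so memory stays bounded and the per-cell fits are
embarrassingly parallel.

The resulting score matrix V is *not* re-orthonormalized: each row retains
its per-cell maximum-likelihood interpretation (the fit carries
``orthonormal_V=False``).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .irsvd import IRSVDConfig, fit_gbm
from .model_core import CountMatrix, GBMFit, as_count_matrix, check_margins

logger = logging.getLogger(__name__)


def subsample_cells(Y, n_sub: int, seed: int | np.random.Generator = 0):
    """Uniform without-replacement cell subset; returns (Y_sub, index array)."""
    Y = as_count_matrix(Y)
    J = Y.n_cells
    if not 1 <= n_sub <= J:
        raise ValueError(f"n_sub={n_sub} out of range [1, {J}]")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    idx = np.sort(rng.choice(J, size=n_sub, replace=False))
    sub = CountMatrix(
        Y.values[:, idx].tocsr(),
        list(Y.gene_ids),
        [Y.cell_ids[j] for j in idx],
    )
    return sub, idx


def fit_cell(
    y_col: np.ndarray,
    alpha: np.ndarray,
    U: np.ndarray,
    sigma: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-8,
    cap: float = 30.0,
):
    """Fit one cell's (beta_j, v_j) by Poisson IRLS at fixed gene-side parameters.

    The linear predictor is ``alpha_i + beta_j + sum_m u_im gamma_jm`` with
    ``gamma_jm = sigma_m v_jm``; the design is [1, U] with offset alpha.
    Returns ``(beta_j, v_j, converged)``.  On divergence the coefficients
    from the best (highest-likelihood) step are returned with a flag.
    """
    y = np.asarray(y_col, dtype=float).ravel()
    alpha = np.asarray(alpha, dtype=float).ravel()
    I = len(y)
    if y.sum() <= 0:
        raise ValueError("cell has zero total counts; filter before projecting")
    M = U.shape[1] if U.ndim == 2 else 0
    D = np.column_stack([np.ones(I), U]) if M else np.ones((I, 1))
    coef = np.zeros(M + 1)
    coef[0] = np.log(y.sum()) - np.log(np.sum(np.exp(np.minimum(alpha, cap))))

    def ll(c):
        eta = alpha + D @ c
        return np.sum(y * eta) - np.sum(np.exp(np.minimum(eta, cap)))

    best_coef, best_ll = coef.copy(), ll(coef)
    converged = False
    for _ in range(max_iter):
        eta = np.minimum(alpha + D @ coef, cap)
        mu = np.exp(eta)
        grad = D.T @ (y - mu)
        H = D.T @ (mu[:, None] * D)
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving to keep the likelihood non-decreasing
        step = 1.0
        for _ in range(20):
            cand = coef + step * delta
            if ll(cand) >= best_ll - 1e-12:
                break
            step *= 0.5
        coef = coef + step * delta
        cur = ll(coef)
        if cur > best_ll:
            best_ll, best_coef = cur, coef.copy()
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break
    if not converged:
        coef = best_coef
    beta_j = float(coef[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        v_j = coef[1:] / np.asarray(sigma, dtype=float) if M else np.zeros(0)
    return beta_j, v_j, converged


def fit_gbm_projected(
    Y,
    cfg: IRSVDConfig | None = None,
    n_sub: int = 1000,
    seed: int = 0,
    refit_subset: bool = True,
    **cfg_kwargs,
) -> GBMFit:
    """Two-stage fit: IRSVD on a random cell subset, then per-cell projection.

    All cells (including subset cells, for a single provenance of V) are
    refit independently by :func:`fit_cell`; set ``refit_subset=False`` to
    keep subset cells' scores from the subset fit.  Deterministic given
    (Y, cfg, n_sub, seed).
    """
    if cfg is None:
        cfg = IRSVDConfig(**cfg_kwargs)
    Y = as_count_matrix(Y)
    check_margins(Y)
    if n_sub < cfg.M + 2:
        raise ValueError(f"n_sub={n_sub} must be at least M+2={cfg.M + 2}")
    n_sub = min(n_sub, Y.n_cells)
    Y_sub, idx = subsample_cells(Y, n_sub, seed)
    sub_fit = fit_gbm(Y_sub, cfg)
    if not sub_fit.converged:
        warnings.warn("subset IRSVD fit did not converge; projection proceeds "
                      "from its best iterate", RuntimeWarning)
    alpha, U, sigma = sub_fit.alpha, sub_fit.U, sub_fit.sigma
    M = len(sigma)
    J = Y.n_cells
    beta = np.empty(J)
    V = np.empty((J, M))
    n_diverged = 0
    in_subset = np.zeros(J, dtype=bool)
    in_subset[idx] = True
    sub_pos = {j: k for k, j in enumerate(idx)}
    for j in range(J):
        if not refit_subset and in_subset[j]:
            beta[j] = sub_fit.beta[sub_pos[j]]
            V[j] = sub_fit.V[sub_pos[j]]
            continue
        y = np.asarray(Y.values[:, [j]].todense()).ravel()
        b, v, ok = fit_cell(y, alpha, U, sigma, cap=cfg.cap)
        beta[j], V[j] = b, v
        n_diverged += not ok
    if n_diverged:
        warnings.warn(f"{n_diverged} per-cell GLM fits did not converge in 25 "
                      "IRLS steps; best-step coefficients kept", RuntimeWarning)
    out = GBMFit(alpha, beta, U, sigma, V, tau=cfg.tau,
                 orthonormal_V=False, converged=sub_fit.converged)
    out.trace = sub_fit.trace
    out.meta = {
        "variant": "projected", "M": cfg.M, "tau": cfg.tau, "seed": seed,
        "n_sub": n_sub, "subset_indices": idx.tolist(),
        "n_cell_fits_diverged": int(n_diverged),
    }
    return out
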