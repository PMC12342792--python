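"""Evaluation metrics and transformation-based PCA baselines.

Metrics: basis-free subspace distance between score matrices, binomial
count splitting for train/test evaluation of count models, held-out Poisson
log-likelihood, and the adjusted Rand index.  Baselines: the standard
log-normalization PCA pipelines (with and without per-gene scaling) and PCA
on analytic Pearson residuals.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .model_core import CountMatrix, as_count_matrix


def subspace_distance(V_hat: np.ndarray, V: np.ndarray) -> float:
    """Frobenius distance between projectors onto the two column spaces.

    ``||Pi_Vhat - Pi_V||_F`` computed from principal angles (via QR), never
    materializing the J x J projectors.  Zero iff the column spaces agree;
    for disjoint M-dimensional subspaces the value is sqrt(2M).
    """
    V_hat = np.atleast_2d(np.asarray(V_hat, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if V_hat.shape[0] != V.shape[0]:
        raise ValueError("score matrices differ in number of cells")
    for name, A in (("V_hat", V_hat), ("V", V)):
        if np.linalg.matrix_rank(A) < A.shape[1]:
            raise ValueError(f"{name} is rank-deficient")
    Q1 = np.linalg.qr(V_hat)[0]
    Q2 = np.linalg.qr(V)[0]
    c = np.linalg.svd(Q1.T @ Q2, compute_uv=False)
    sq = Q1.shape[1] + Q2.shape[1] - 2 * np.sum(c**2)
    return float(np.sqrt(max(sq, 0.0)))


def count_split(Y, p: float = 0.5, rng=0):
    """Entrywise binomial thinning into two matrices summing exactly to Y.

    ``Y_train ~ Binomial(Y, p)`` and ``Y_test = Y - Y_train``.  For Poisson
    counts the two halves are independent Poisson matrices.
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    Y = as_count_matrix(Y)
    train = Y.values.copy()
    train.data = rng.binomial(Y.values.data.astype(np.int64), p)
    test = Y.values - train
    return (
        CountMatrix(train.tocsr(), list(Y.gene_ids), list(Y.cell_ids)),
        CountMatrix(test.tocsr(), list(Y.gene_ids), list(Y.cell_ids)),
    )


def oos_loglik(Y_test, mu_hat: np.ndarray) -> float:
    """Held-out Poisson log-likelihood sum(Y* log mu_hat - mu_hat),
    additive constants removed."""
    Y_test = as_count_matrix(Y_test)
    mu_hat = np.asarray(mu_hat, dtype=float)
    if np.any(mu_hat <= 0):
        raise ValueError("mu_hat must be strictly positive")
    coo = Y_test.values.tocoo()
    return float(
        np.sum(coo.data * np.log(mu_hat[coo.row, coo.col])) - np.sum(mu_hat)
    )


def oracle_oos_loglik(mu_true: np.ndarray, mu_hat: np.ndarray) -> float:
    """Population variant sum(mu log mu_hat - mu_hat) for simulations where
    the generating means are known; maximized at mu_hat = mu_true."""
    mu_true = np.asarray(mu_true, dtype=float)
    mu_hat = np.asarray(mu_hat, dtype=float)
    if np.any(mu_hat <= 0):
        raise ValueError("mu_hat must be strictly positive")
    return float(np.sum(mu_true * np.log(mu_hat)) - np.sum(mu_hat))


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected partition agreement (permutation-model ARI)."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(a, b))


def _pca_scores(Z: np.ndarray, n_pc: int, seed: int = 0) -> np.ndarray:
    """PCA scores of cells (columns of Z); genes are mean-centered features."""
    return PCA(n_components=n_pc, svd_solver="full", random_state=seed).fit_transform(Z.T)


def log_normalize(Y, L: float | None = None) -> np.ndarray:
    """Depth-normalized log transform Z_ij = log(L Y_ij / S_j + 1).

    L defaults to the median cell depth.
    """
    Y = as_count_matrix(Y)
    S = Y.cell_sums().astype(float)
    if np.any(S == 0):
        raise ValueError("cells with zero total counts")
    if L is None:
        L = float(np.median(S))
    return np.log1p(L * Y.dense() / S[None, :])


def log_pca(Y, scale: bool = False, n_pc: int = 2, L: float | None = None) -> np.ndarray:
    """Log-normalization + PCA baselines; returns J x n_pc cell scores.

    ``Z_ij = log(L Y_ij / S_j + 1)`` with size factor L = median depth
    (plain variant) or L = 1e4 followed by per-gene standardization to zero
    mean / unit variance (``scale=True``).  Genes with zero variance after
    transformation are dropped from the scaled variant with a warning.
    """
    if L is None and scale:
        L = 1e4
    Z = log_normalize(Y, L)
    if scale:
        sd = Z.std(axis=1)  # per-gene sd across cells
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} constant gene(s) from the "
                "scaled variant", RuntimeWarning,
            )
        Z = (Z[keep] - Z[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return _pca_scores(Z, n_pc)


def apr_pca(Y, theta: float = 100.0, n_pc: int = 2) -> np.ndarray:
    """PCA on analytic Pearson residuals; returns J x n_pc cell scores.

    Fitted means are the closed-form two-way margins
    ``mu_ij = (row sum)(col sum)/total`` and residuals are
    ``(Y - mu)/sqrt(mu + mu^2/theta)`` with fixed dispersion theta.
    theta -> inf recovers plain Poisson Pearson residuals.
    """
    Y = as_count_matrix(Y)
    gs = Y.gene_sums().astype(float)
    cs = Y.cell_sums().astype(float)
    total = gs.sum()
    if total <= 0 or np.any(gs == 0) or np.any(cs == 0):
        raise ValueError("zero margins")
    mu = np.outer(gs, cs) / total
    Z = (Y.dense() - mu) / np.sqrt(mu + mu**2 / theta)
    return _pca_scores(Z, n_pc)
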