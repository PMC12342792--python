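"""Poisson bilinear model for UMI count matrices.

The model for a genes x cells count matrix ``Y`` (I genes, J cells) is

    Y_ij ~ Poisson(mu_ij),   log mu_ij = alpha_i + beta_j + sum_m sigma_m u_im v_jm

with gene intercepts ``alpha``, cell intercepts ``beta`` (both on the
natural-log scale), orthonormal loadings ``U`` (I x M), orthonormal scores
``V`` (J x M) and positive scale factors ``sigma`` sorted non-increasing.
The low-rank interaction is written ``X = U diag(sigma) V^T``.  An optional
Exponential(tau) prior on each sigma_m penalizes the nuclear norm of X and
stabilizes the fit.

This module holds the data containers, the mean/likelihood computations and
the canonical (identifiable) parameterization shared by every other module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: default cap on the linear predictor (natural-log scale) guarding exp overflow
DEFAULT_CAP = 30.0


class OverflowCapError(ValueError):
    """Linear predictor exceeded the configured cap."""


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of non-negative integer UMI counts."""

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        self.values = self.values.tocsr()
        I, J = self.values.shape
        if I < 1 or J < 1:
            raise ValueError("count matrix must have at least one gene and one cell")
        if len(self.gene_ids) != I or len(self.cell_ids) != J:
            raise ValueError(
                f"identifier lists ({len(self.gene_ids)}, {len(self.cell_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                i, j = _first_offender(self.values, data < 0)
                raise ValueError(f"negative count at gene {i}, cell {j}")
            if not np.allclose(data, np.round(data)):
                i, j = _first_offender(self.values, ~np.isclose(data, np.round(data)))
                raise ValueError(f"non-integer count at gene {i}, cell {j}")
        self.values.data = np.round(data).astype(np.int64)

    @classmethod
    def from_dense(cls, Y, gene_ids=None, cell_ids=None) -> "CountMatrix":
        Y = np.asarray(Y)
        I, J = Y.shape
        if gene_ids is None:
            gene_ids = [f"gene{i}" for i in range(I)]
        if cell_ids is None:
            cell_ids = [f"cell{j}" for j in range(J)]
        return cls(sp.csr_matrix(Y), list(gene_ids), list(cell_ids))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Dense float copy of the counts (one I x J working array)."""
        return np.asarray(self.values.todense(), dtype=float)

    def gene_sums(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def cell_sums(self) -> np.ndarray:
        """Per-cell total counts S_j (sequencing depth)."""
        return np.asarray(self.values.sum(axis=0)).ravel()


def _first_offender(mat: sp.csr_matrix, mask: np.ndarray) -> tuple[int, int]:
    # csr data order is preserved by tocoo
    coo = mat.tocoo()
    k = int(np.flatnonzero(mask)[0])
    return int(coo.row[k]), int(coo.col[k])


def as_count_matrix(Y) -> CountMatrix:
    """Coerce an array / sparse matrix / CountMatrix to a CountMatrix."""
    if isinstance(Y, CountMatrix):
        return Y
    if sp.issparse(Y):
        Y = np.asarray(Y.todense())
    return CountMatrix.from_dense(Y)


@dataclass
class GBMFit:
    """Fitted (or true) parameters of the Poisson bilinear model.

    Invariants (canonical form): ``U^T U = V^T V = I_M`` to 1e-8, sigma
    sorted non-increasing and strictly positive, and for each factor the
    largest-|entry| element of the loading column is positive.  Projection
    fits relax the orthonormality of V (``orthonormal_V=False``).
    """

    alpha: np.ndarray
    beta: np.ndarray
    U: np.ndarray
    sigma: np.ndarray
    V: np.ndarray
    tau: float = 0.0
    trace: list = field(default_factory=list)
    converged: bool = True
    orthonormal_V: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        self.U = np.asarray(self.U, dtype=float).reshape(len(self.alpha), -1)
        self.V = np.asarray(self.V, dtype=float).reshape(len(self.beta), -1)

    @property
    def M(self) -> int:
        return len(self.sigma)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.alpha), len(self.beta)

    def interaction(self) -> np.ndarray:
        """The low-rank interaction X = U diag(sigma) V^T (dense I x J)."""
        if self.M == 0:
            return np.zeros(self.shape)
        return (self.U * self.sigma) @ self.V.T

    def scores(self) -> np.ndarray:
        """Scaled cell scores V diag(sigma) (J x M), the embedding to plot/cluster."""
        return self.V * self.sigma

    def validate(self, tol: float = 1e-8) -> None:
        M = self.M
        if M:
            if np.any(self.sigma <= 0):
                raise ValueError("sigma entries must be strictly positive")
            if np.any(np.diff(self.sigma) > tol):
                raise ValueError("sigma must be non-increasing")
            if not np.allclose(self.U.T @ self.U, np.eye(M), atol=tol):
                raise ValueError("U columns are not orthonormal")
            if self.orthonormal_V and not np.allclose(
                self.V.T @ self.V, np.eye(M), atol=tol
            ):
                raise ValueError("V columns are not orthonormal")


def linear_predictor(fit: GBMFit) -> np.ndarray:
    return fit.alpha[:, None] + fit.beta[None, :] + fit.interaction()


def mean_matrix(fit: GBMFit, cap: float = DEFAULT_CAP) -> np.ndarray:
    """Fitted Poisson means mu_ij = exp(alpha_i + beta_j + X_ij).

    Raises :class:`OverflowCapError` naming offending indices when any
    entry of the linear predictor exceeds ``cap``.
    """
    eta = linear_predictor(fit)
    if np.any(eta > cap):
        idx = np.argwhere(eta > cap)
        shown = ", ".join(f"(gene {i}, cell {j})" for i, j in idx[:5])
        raise OverflowCapError(
            f"linear predictor exceeds cap {cap} at {idx.shape[0]} entries: {shown}"
        )
    return np.exp(eta)


def log_likelihood(Y, fit: GBMFit, cap: float = DEFAULT_CAP) -> float:
    """Poisson log-likelihood sum_ij (Y_ij log mu_ij - mu_ij).

    Additive constants -log(Y_ij!) are removed, so the value is comparable
    across fits on the same counts but is not an absolute log-probability.
    """
    Y = as_count_matrix(Y)
    if Y.shape != fit.shape:
        raise ValueError(f"count matrix {Y.shape} does not match fit {fit.shape}")
    eta = linear_predictor(fit)
    if np.any(eta > cap):
        mean_matrix(fit, cap=cap)  # raise with indices
    # sum Y*eta computed sparsely; sum exp(eta) densely
    coo = Y.values.tocoo()
    return float(np.sum(coo.data * eta[coo.row, coo.col]) - np.sum(np.exp(eta)))


def log_posterior(Y, fit: GBMFit, cap: float = DEFAULT_CAP) -> float:
    """Log-posterior: log-likelihood minus the Exponential(tau) prior penalty.

    Under the canonical form the nuclear norm of X is sum(sigma), so the
    prior contributes ``-tau * sum(sigma)`` up to constants.
    """
    return log_likelihood(Y, fit, cap=cap) - fit.tau * float(np.sum(fit.sigma))


def canonicalize(
    alpha,
    beta,
    U_raw,
    sigma_raw,
    V_raw,
    tau: float = 0.0,
    center_factors: bool = True,
    drop_tol: float = 1e-12,
    **fit_kwargs,
) -> GBMFit:
    """Return an equivalent parameterization in canonical form.

    The mean matrix is preserved exactly (to floating point).  When
    ``center_factors`` is on, row and column means of X are absorbed into
    the intercepts (double-centering), removing the remaining gauge freedom
    between intercepts and factors.  Zero singular values are dropped with
    a warning, reducing M.
    """
    alpha = np.asarray(alpha, dtype=float).ravel().copy()
    beta = np.asarray(beta, dtype=float).ravel().copy()
    sigma_raw = np.atleast_1d(np.asarray(sigma_raw, dtype=float))
    U_raw = np.asarray(U_raw, dtype=float).reshape(len(alpha), -1)
    V_raw = np.asarray(V_raw, dtype=float).reshape(len(beta), -1)
    if np.any(sigma_raw < 0):
        raise ValueError("sigma_raw must be non-negative")
    M = len(sigma_raw)
    if M == 0:
        return GBMFit(alpha, beta, U_raw[:, :0], sigma_raw, V_raw[:, :0],
                      tau=tau, **fit_kwargs)
    for name, F in (("U", U_raw), ("V", V_raw)):
        if np.linalg.matrix_rank(F) < F.shape[1]:
            raise ValueError(f"{name}_raw is rank-deficient")

    X = (U_raw * sigma_raw) @ V_raw.T
    if center_factors:
        r = X.mean(axis=1)
        c = X.mean(axis=0)
        g = X.mean()
        X = X - r[:, None] - c[None, :] + g
        alpha = alpha + r
        beta = beta + c - g

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    keep = s > max(drop_tol, drop_tol * (s[0] if s.size else 1.0))
    keep &= np.arange(len(s)) < M
    if keep.sum() < min(M, len(s)):
        warnings.warn(
            f"dropping {int(min(M, len(s)) - keep.sum())} zero singular value(s); "
            f"rank reduced to {int(keep.sum())}",
            RuntimeWarning,
        )
    U, s, V = U[:, keep], s[keep], Vt[keep].T
    U, V = fix_signs(U, V)
    return GBMFit(alpha, beta, U, s, V, tau=tau, **fit_kwargs)


def fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip factor signs so each loading column's largest-|entry| is positive."""
    U = U.copy()
    V = V.copy()
    for m in range(U.shape[1]):
        k = int(np.argmax(np.abs(U[:, m])))
        if U[k, m] < 0:
            U[:, m] = -U[:, m]
            V[:, m] = -V[:, m]
    return U, V


def check_margins(Y: CountMatrix) -> None:
    """Reject all-zero genes or zero-depth cells (their intercept MLE is -inf)."""
    gs = Y.gene_sums()
    cs = Y.cell_sums()
    if np.any(gs == 0):
        raise ValueError(
            f"{int(np.sum(gs == 0))} gene(s) have all-zero counts "
            "(e.g. index %d); filter with drop_zero_margins" % int(np.argmin(gs > 0))
        )
    if np.any(cs == 0):
        raise ValueError(
            f"{int(np.sum(cs == 0))} cell(s) have zero total counts; "
            "filter with drop_zero_margins"
        )


def drop_zero_margins(Y) -> CountMatrix:
    """Drop all-zero genes and zero-depth cells, logging what was removed."""
    Y = as_count_matrix(Y)
    gs = Y.gene_sums()
    cs = Y.cell_sums()
    keep_g = gs > 0
    keep_c = cs > 0
    if keep_g.all() and keep_c.all():
        return Y
    logger.info(
        "dropping %d all-zero genes and %d zero-count cells",
        int((~keep_g).sum()), int((~keep_c).sum()),
    )
    sub = Y.values[keep_g][:, keep_c]
    return CountMatrix(
        sub.tocsr(),
        [g for g, k in zip(Y.gene_ids, keep_g) if k],
        [c for c, k in zip(Y.cell_ids, keep_c) if k],
    )
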