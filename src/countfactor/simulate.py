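"""Synthetic data generators.

Three generators cover the study conditions used throughout the tests:

* :func:`simulate_gbm` — counts from the Poisson bilinear model itself, with
  loadings/scores drawn uniformly from the Stiefel manifold, singular values
  ``sigma_m = (kappa m / M)(sqrt(I) + sqrt(J))`` and standard-normal
  intercepts.  ``kappa`` controls the latent signal strength.
* :func:`simulate_marker_genes` — four cell types distinguished only by two
  marker genes (gene 1: moderate/low/high/high; gene 2: low/low/low/high)
  against a backdrop of i.i.d. Poisson(1) null genes, with two rare and two
  common types.  The regime where transformation+PCA pipelines lose the
  rare types.
* :func:`simulate_null_poisson` — homogeneous Poisson noise, the null for
  cluster-significance calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import CountMatrix, GBMFit, mean_matrix

__all__ = [
    "SimTruth", "MarkerSimConfig", "sample_stiefel", "simulate_gbm",
    "simulate_marker_genes", "simulate_null_poisson", "downsample_by_label",
]


@dataclass
class SimTruth:
    """Ground-truth parameters behind a simulated count matrix."""

    alpha: np.ndarray
    beta: np.ndarray
    U: np.ndarray
    sigma: np.ndarray
    V: np.ndarray
    mu: np.ndarray
    labels: np.ndarray | None = None

    def as_fit(self) -> GBMFit:
        return GBMFit(self.alpha, self.beta, self.U, self.sigma, self.V)


@dataclass
class MarkerSimConfig:
    """Four-cell-type marker-gene simulation settings.

    Defaults: two rare types (A, B: 25 cells each) and two common types
    (C, D: 475 each), 1000 cells total.  Gene 1 means are moderate/low/
    high/high over (A, B, C, D); gene 2 means are low/low/low/high; the
    remaining ``n_null_genes`` genes are i.i.d. Poisson(``null_rate``).
    """

    n_cells: tuple[int, int, int, int] = (25, 25, 475, 475)
    gene1_means: tuple[float, float, float, float] = (3.0, 0.3, 10.0, 10.0)
    gene2_means: tuple[float, float, float, float] = (0.3, 0.3, 0.3, 10.0)
    n_null_genes: int = 998
    null_rate: float = 1.0

    def __post_init__(self) -> None:
        g1 = self.gene1_means
        g2 = self.gene2_means
        if min(g1) <= 0 or min(g2) <= 0 or self.null_rate <= 0:
            raise ValueError("all means must be positive")
        # A moderate, B low, C/D high for gene 1; D high for gene 2
        if not (g1[1] < g1[0] < g1[2] and g1[1] < g1[0] < g1[3]):
            raise ValueError("gene 1 means must satisfy low(B) < moderate(A) < high(C, D)")
        if not (max(g2[0], g2[1], g2[2]) < g2[3]):
            raise ValueError("gene 2 means must satisfy low(A, B, C) < high(D)")


def _as_rng(rng) -> np.random.Generator:
    return np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng


def sample_stiefel(n: int, M: int, rng=0) -> np.ndarray:
    """Uniform (Haar) draw of an n x M matrix with orthonormal columns.

    QR of a standard Gaussian matrix with the sign fix making the diagonal
    of R positive, which yields exact Haar distribution.
    """
    if M > n:
        raise ValueError(f"M={M} exceeds n={n}")
    rng = _as_rng(rng)
    Q, R = np.linalg.qr(rng.standard_normal((n, M)))
    return Q * np.sign(np.diag(R))


def simulate_gbm(I: int, J: int, M: int, kappa: float, rng=0):
    """Counts from the Poisson bilinear model.

    ``sigma_m = (kappa m / M)(sqrt(I) + sqrt(J))`` for m = 1..M (stored
    sorted decreasing with factors reordered — the spanned subspace is
    unchanged), U and V Haar-orthonormal, intercepts i.i.d. N(0, 1).
    Returns (CountMatrix, SimTruth).
    """
    if M > min(I, J):
        raise ValueError("M must not exceed min(I, J)")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    rng = _as_rng(rng)
    U = sample_stiefel(I, M, rng)
    V = sample_stiefel(J, M, rng)
    sigma = kappa * np.arange(1, M + 1) / M * (np.sqrt(I) + np.sqrt(J))
    # store non-increasing: reverse factor order
    U, sigma, V = U[:, ::-1].copy(), sigma[::-1].copy(), V[:, ::-1].copy()
    alpha = rng.standard_normal(I)
    beta = rng.standard_normal(J)
    truth_fit = GBMFit(alpha, beta, U, sigma, V)
    mu = mean_matrix(truth_fit)  # raises on overflow past the cap
    Y = rng.poisson(mu)
    return (
        CountMatrix.from_dense(Y),
        SimTruth(alpha, beta, U, sigma, V, mu=mu),
    )


def simulate_marker_genes(cfg: MarkerSimConfig | None = None, rng=0):
    """Four-type marker-gene counts; returns (CountMatrix, labels).

    Labels are integers 0..3 for types A..D.
    """
    cfg = cfg or MarkerSimConfig()
    rng = _as_rng(rng)
    sizes = np.asarray(cfg.n_cells)
    J = int(sizes.sum())
    labels = np.repeat(np.arange(4), sizes)
    g1 = np.repeat(cfg.gene1_means, sizes)
    g2 = np.repeat(cfg.gene2_means, sizes)
    Y = np.empty((2 + cfg.n_null_genes, J), dtype=np.int64)
    Y[0] = rng.poisson(g1)
    Y[1] = rng.poisson(g2)
    Y[2:] = rng.poisson(cfg.null_rate, size=(cfg.n_null_genes, J))
    gene_ids = ["marker1", "marker2"] + [f"null{i}" for i in range(cfg.n_null_genes)]
    return CountMatrix.from_dense(Y, gene_ids=gene_ids), labels


def simulate_null_poisson(I: int, J: int, rate: float = 1.0, rng=0) -> CountMatrix:
    """Homogeneous i.i.d. Poisson(rate) counts (no structure)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = _as_rng(rng)
    return CountMatrix.from_dense(rng.poisson(rate, size=(I, J)))


def downsample_by_label(Y: CountMatrix, labels, keep: dict, rng=0):
    """Keep at most ``keep[label]`` cells of each label (utility for creating
    class-imbalanced subsets); returns (CountMatrix, labels, indices)."""
    rng = _as_rng(rng)
    labels = np.asarray(labels)
    chosen: list[int] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        n = min(keep.get(lab, len(idx)), len(idx))
        chosen.extend(rng.choice(idx, size=n, replace=False))
    chosen = np.sort(np.asarray(chosen))
    sub = CountMatrix(
        Y.values[:, chosen].tocsr(),
        list(Y.gene_ids),
        [Y.cell_ids[j] for j in chosen],
    )
    return sub, labels[chosen], chosen
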