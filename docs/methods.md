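# Methods

## Model

`countfactor` models a genes × cells UMI count matrix `Y ∈ N^{I×J}` with a
Poisson generalized bilinear model (GBM):

    Y_ij ~ Poisson(μ_ij),    log μ_ij = α_i + β_j + Σ_m σ_m u_im v_jm

The gene intercepts `α` absorb average expression, the cell intercepts `β`
absorb sequencing depth, and the rank-M interaction `X = UΣVᵀ` carries the
biological structure: `U` (I×M) are gene loadings, `V` (J×M) are cell
scores, `σ_1 ≥ … ≥ σ_M > 0` are scale factors. This is PCA moved inside the
log link of a Poisson GLM: normalization, variance stabilization and
factorization happen in one model instead of a transform-then-PCA pipeline.
An optional Exponential(τ) prior on each `σ_m` (equivalently a nuclear-norm
penalty `τ‖X‖₊` in the canonical form) shrinks weak factors; the default is
τ = 0 so the default fit is the (penalized-by-nothing) MLE.

The Poisson outcome is deliberate: UMI technical noise is very close to
Poisson, and apparent overdispersion is the biological heterogeneity the
factors are meant to capture, so an overdispersed outcome family would
compete with the factorization for the signal.

### Identifiability

The factorization is made unique by: orthonormal `U` and `V`, `σ`
non-increasing and positive, a sign convention (the largest-|entry| element
of each loading column is positive), and — because intercepts can trade off
against factors — double-centering: row and column means of `X` are
absorbed into `α` and `β` (`center_factors=True`, default; switchable for
experiments that need the raw factorization). `canonicalize` converts any
parameterization into this form while preserving `μ` exactly. Simulation
truths are put through the same canonicalization before being compared to
fits, so comparisons are made in a single gauge.

Genes with all-zero counts and cells with zero depth are rejected (their
intercept MLE is −∞); `drop_zero_margins` filters them with logging.

## Estimation: iteratively reweighted SVD (IRSVD)

A second-order Taylor expansion of the log-posterior at the current
estimates reduces the `X` update to a weighted low-rank problem with
weights `W_ij = μ̂_ij/μ̂*` (μ̂* the largest fitted mean) and working response
`Z_ij = X̂_ij + (Y_ij−μ̂_ij)/μ̂_ij`. One soft-impute step solves it:

    X̂ ← SVD_{M,τ}( X̂ + (Y − μ̂)/μ̂* )

where `SVD_{M,τ}` is the rank-M truncated SVD with singular values
soft-thresholded by τ. The identity `W∘(Z−X̂) = (Y−μ̂)/μ̂*` means only one
dense I×J working array is ever formed. With `X̂` fixed, the intercepts have
closed-form maximum-likelihood updates computed for all genes (then all
cells) simultaneously. One outer iteration is one X step plus one α-then-β
sweep; orthonormality of the factors holds after every iteration because
each X comes out of an SVD.

**Step-length adaptation.** The plain update is a gradient step of length
1/μ̂* on X, which is a global-curvature bound: when fitted means are
heterogeneous (they always are, on log-normal-like intercepts) it is far
too conservative — small-mean entries move at rate μ_ij/μ̂* and convergence
can take tens of thousands of iterations. `fit_gbm` therefore scales the
residual term by an adaptive step length: grown geometrically while the
penalized objective keeps improving, halved (up to 8 times within an
iteration, also on overflow of the cap) when it would decrease by more than
1e-8. The update direction and the fixed points are unchanged; the
objective is monotone by construction. On a 6×6 instance this reduces the
gap to a directly-optimized MLE from 0.26 nats after 60 000 plain
iterations to 3e-9 after 12 adapted ones.

**Convergence** is declared when the relative change of the penalized
log-posterior falls below `tol` (default 1e-6; the defaults `max_iter=100`,
`tol=1e-6` suit exploratory fits — the tests and the acceptance script use
`tol=1e-8` and larger iteration caps where score geometry, not deviance, is
being measured, because near-optimal deviance can coexist with slowly
settling factors). Non-convergence returns the best iterate with a warning,
never silently. The truncated SVD uses LAPACK for small matrices and ARPACK
(`svds` with a fixed, seed-derived start vector) otherwise, so fits are
deterministic given `(Y, config)`.

**Initialization**: `β_j = log S_j − mean(log S)` (centered log depths),
`α_i` the matching closed form, `X̂ = 0`. The initial means are exactly
`(row sum)(col sum)/total` — the two-way margin model that also underlies
analytic Pearson residuals; `M=0` reproduces it exactly.

**Degenerate MLEs.** On tiny matrices containing zeros, the unpenalized
rank-1 MLE need not exist: the likelihood can increase without bound along
directions sending some means to zero (we observed a direct optimizer
climbing past σ̂ ≈ 6500 on a 6×6 with five zeros). Optimizer-equivalence
checks therefore use strictly positive count instances, where the MLE
exists; on real-sized data this degeneracy is not reached in practice, and
τ > 0 removes it entirely.

## Scaling to many cells: subsample and project

`fit_gbm_projected` fits (α, U, Σ) by IRSVD on a uniformly chosen subset of
`n_sub` cells, freezes them, and fits every cell's `(β_j, v_j)`
independently: at fixed `U`, column j of the model is an ordinary Poisson
GLM with design `[1, U]`, offset α and coefficients `(β_j, σ_1v_j1, …)`.
The per-cell solver is IRLS with step-halving, at most 25 steps, tolerance
1e-8 on the coefficient change; each column is processed on its own, so
memory stays bounded and the loop parallelizes trivially. All cells
(including subset cells) are refit by projection so `V` has one provenance
(`refit_subset=False` keeps subset scores instead). The projected `V` is
deliberately *not* re-orthonormalized — each row is a per-cell ML estimate
— and the fit is flagged `orthonormal_V=False`.

## Uncertainty in the scores

The Fisher information for cell j's score vector is the M×M block

    F_j = (UΣ)ᵀ diag(μ_1j…μ_Ij) (UΣ)

and `se(v̂_jm) = sqrt([F_j⁻¹]_mm)` with the fitted means plugged in.
Treating α, β, U, Σ as fixed makes these *underestimates*; empirically the
pooled coverage of 95% normal intervals on model-generated data is ~0.92 at
I=J=500 (the acceptance suite recomputes this). Loading standard errors use
the transposed computation `G_i = (VΣ)ᵀ diag(μ_i·) (VΣ)`. Singular blocks
fall back to pseudo-inverse values with a warning.

## Cluster cohesion index (CCI)

Given a base clustering of the scaled embedding `V̂Σ̂` (Louvain on a
20-nearest-neighbor graph at resolution 0.8 by default; a k-means backend
exists for deterministic checks and known K), each repetition draws
`ṽ_jm ~ N(v̂_jm, se_jm²)` independently, reclusters `ṼΣ̂` with the same
method descriptor and a fresh seed (so algorithmic stochasticity is
included), and records for every ordered cluster pair the fraction of cell
pairs co-clustered. The CCI of cluster k is the mean within-k fraction over
repetitions (default 100); the inter-CCI matrix holds the cross-cluster
fractions, is symmetric, and has the CCIs on its diagonal. Singleton
clusters have no pairs and are reported as missing.

**Significance threshold.** The null model is V = 0: no structure beyond
intercepts. The default calibration is a parametric bootstrap of the whole
pipeline — simulate `Y⁰ ~ Poisson(exp(α̂+β̂))`, refit at the same rank,
compute standard errors, cluster, estimate that clustering's CCIs — because
an embedding *fitted* to pure noise inherits structure from the noise that
directly drawn `N(0, se²)` scores do not have; the direct draws (kept as
`mode="gaussian"`) give CCIs that are systematically too low and hence an
anti-conservative threshold. Null CCIs are aggregated per repetition by
their maximum (default), so comparing every observed cluster against the
0.95 quantile controls the familywise chance that any null cluster
exceeds the threshold; `aggregate="pooled"` gives the per-cluster “raw”
level instead.

## Synthetic data generators

* `simulate_gbm(I, J, M, kappa)` draws `U`, `V` uniformly from the Stiefel
  manifold (QR of a Gaussian matrix with the positive-diagonal sign fix,
  which is exactly Haar), sets `σ_m = (κm/M)(√I + √J)` (stored sorted
  decreasing; the spanned subspace is unchanged), intercepts i.i.d. N(0,1),
  and Poisson counts from the model. κ controls latent signal strength; at
  κ = 2 the weakest factors sit near the detection limit, which is the
  regime the recovery experiments probe.
* `simulate_marker_genes` draws four cell types distinguished only by two
  marker genes over a backdrop of 998 Poisson(1) null genes. Defaults (our
  choice, config-exposed): rare types A, B with 25 cells each, common types
  C, D with 475 each; gene-1 means (3, 0.3, 10, 10) — moderate, low, high,
  high — and gene-2 means (0.3, 0.3, 0.3, 10). This is the regime where
  transform-then-PCA pipelines bury the two marker genes' variance below
  the null-gene noise floor.
* `simulate_null_poisson` gives i.i.d. Poisson(rate) counts, the
  cluster-significance null.

What these generators do **not** emulate: gene-gene correlation beyond the
low-rank term, batch effects, zero inflation beyond Poisson sparsity, or
realistic library-size distributions (log-normal-ish via N(0,1) intercepts
only). Passing tests show correctness of the machinery under the model's
own assumptions, not robustness to their violation.

## Evaluation utilities

* `subspace_distance` is `‖Π_V̂ − Π_V‖_F`, computed from principal angles
  via QR without forming J×J projectors; basis-free, `√(2M)` for disjoint
  subspaces.
* `count_split` thins `Y_train ~ Binomial(Y, p)` entrywise (p = 1/2 by
  default), `Y_test = Y − Y_train`; for Poisson counts the halves are
  independent, giving honest train/test splits. `oos_loglik` is the
  held-out Poisson log-likelihood with additive constants removed;
  `oracle_oos_loglik` is the population variant `Σ μ log μ̂ − μ̂` for
  simulations.
* Baselines: `log_pca` (`Z = log(L·Y/S + 1)`, L = median depth, PCA with
  gene-wise centering) and its scaled variant (L = 1e4, per-gene
  standardization, zero-variance genes dropped); `apr_pca` (Pearson
  residuals of the two-way margin model with fixed dispersion θ = 100).
  Neither applies highly-variable-gene selection. `adjusted_rand_index`
  is the standard permutation-model ARI.

## Problem sizes and numerical choices

The test and acceptance workloads use: recovery at I=300, J=1000, M=5,
κ=2; coverage over 20 replicate fits at I=J=500, M=2, κ=2 (κ unstated by
the protocol; chosen to match the recovery study); CCI calibration over 10
null datasets at I=300, J=1000 with rank M=5 (a lean rank keeps the
spurious-cluster count moderate) with 20 perturbation and 20×20 bootstrap
repetitions rather than the library default 100. The linear-predictor cap
is 30 on the natural-log scale (exp overflow guard, configurable).
Soft-thresholding uses exactly τ (not τ/μ̂*), a documented choice kept
switch-free because the default τ = 0 makes it moot.

## Known limitations

* The block-diagonal Fisher approximation underestimates score
  uncertainty; intervals are mildly anti-conservative even on
  model-generated data.
* Subspace recovery of weak factors (σ_m not far above `(IJ μ̄)^{1/4}`
  scale) is limited by information, not optimization: an oracle knowing
  the true loadings does no better. Reported subspace distances at κ=2
  reflect that statistical floor.
* IRSVD densifies the working matrix; memory is O(IJ) for the full fit
  (the projection path is the intended route for very large J).
* The CCI measures stability under the fitted model's own uncertainty; it
  cannot detect model misspecification.
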