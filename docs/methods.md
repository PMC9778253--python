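# Methods

## Model

`gkblup` fits a Bayesian multi-trait kernel GBLUP for plant-breeding trials
laid out as lines × environments.  For the n×nT phenotype matrix Y, ordered
first by environment and then by line,

    Y = 1_n μᵀ + X_E β_E + Z_L g + u_gE + ε,

* μ (nT) — trait intercepts; X_E β_E — environment main effects (flat prior,
  sum-to-zero contrasts so the intercept is identified);
* g ~ MN(0, K, Σ_T) — line main effects, K a J×J marker kernel, Σ_T the
  genetic trait covariance;
* u_gE ~ MN(0, K_gE, Σ_TgE) — genotype×environment effects with
  K_gE = (Z_E Z_Eᵀ) ⊙ (Z_L K Z_Lᵀ), i.e. kernel similarity within an
  environment and zero across environments;
* ε ~ MN(0, I_n, R) — residuals, R the residual trait covariance.

The GE term is carried at the *observation* level (an n×nT effect with the
n×n covariance above).  A cell-level J·I formulation is only well defined for
balanced layouts; the observation-level form is identical there (the
incidence matrix is a permutation) and remains well defined when cells are
missing.  The cell-grid summary `gE_hat` is scattered back after the fit,
with unobserved cells at their prior mean 0.

Σ_T, Σ_TgE and R carry independent inverse-Wishart priors, by default
IW(ν = nT+2, S = I): weakly informative, the smallest ν with a finite prior
mean.  The GE trait covariance is a separate parameter from Σ_T even though
both play the "trait covariance" role; tying them would force the GE signal
to scale with the main genetic signal.

### Kernels

The Gaussian kernel is K(x_i,x_j) = exp(−γ‖x_i−x_j‖²), reparameterized as
ρ^{‖x_i−x_j‖²} with ρ = e^(−γ) ∈ (0,1).  Squared Euclidean distances between
marker rows are divided by their maximum, so d² ∈ [0,1].  No universal
convention exists for this normalizer; max-scaling is chosen because it makes
the whole bandwidth interval informative — K = ρ^{d²} then spans (ρ, 1], so
the grid bounds 0.01–0.999 and the untuned choice γ = 1 are all
non-degenerate.  The scale factor is stored for reproducibility.  A VanRaden
genomic relationship matrix (columns centered at 2f_j, cross-product scaled
by 2Σf_j(1−f_j)) is provided as the linear comparator.  Kernels are PSD by
construction; a 1e−8 diagonal jitter is added (and logged) only if the
smallest eigenvalue falls below 1e−10.

### Gibbs sampler

Each sweep:

1. **Data augmentation.**  Missing cells — truly missing values and
   cross-validation-masked test cells alike — are drawn from their
   conditional normal given the fitted surface and R (rows grouped by
   missingness pattern).  Test cells are therefore masked, never dropped:
   their line/environment structure still informs the conditionals, and
   their posterior-mean fitted values are the predictions.
2. **Fixed + line effects, jointly.**  The generalized eigendecomposition
   B of (Σ_T, R) (BᵀRB = I, BᵀΣ_TB = Λ) decouples traits; the
   eigendecomposition K = UDUᵀ decouples lines.  Per transformed trait,
   (Θ, a) are drawn from one Gaussian with precision
   [[WᵀW, WᵀZU], [UᵀZᵀW, UᵀZᵀZU + (λ_tD)⁻¹]].  The joint block matters:
   sampling Θ and g separately leaves a slow mode along intercept-vs-mean(g)
   that inflates Monte-Carlo error severalfold.
3. **GE effects** analogously, blockwise per environment (the GE kernel is
   block-diagonal under the canonical row order; balanced layouts reuse the
   single K eigendecomposition for every block).
4. **Covariances** from inverse-Wishart full conditionals, with the kernel
   quadratic forms evaluated in the eigenbasis.

Kernel eigenvalues are floored at a 1e−12 relative level, which silently
shrinks effectively-null directions to zero instead of failing on
semidefinite kernels (e.g. the GRM).  All draws flow from one
`numpy.random.Generator`; identical seed and inputs give identical output.

Defaults: 3000 iterations, 1000 burn-in, thinning 2.  These are desk-scale
settings adequate for J ≲ 400; the tuning loop uses shorter chains (below).

## Tuning strategies

All three strategies share one objective: the inner-cross-validation mean
NRMSE (per-trait NRMSE on the validation cells, averaged over traits, then
over the 5 inner folds).

* **NT** — ρ = e⁻¹ (γ = 1), no inner fitting.
* **GrS** — exhaustive search over 0.01, 0.05, …, 0.97 plus the endpoint
  0.999 (26 values).  The arithmetic progression alone gives 25 values; the
  stated upper bound is appended to honor both the count and the range.
  Ties break toward the smallest ρ.
* **BO** — Gaussian-process surrogate (Matérn-5/2, constant mean, noise
  1e−6 on the standardized scale: the objective is deterministic given its
  seeds) with expected-improvement acquisition maximized on a 997-point
  lattice in (0.001, 0.999); 6 stratified-jittered starts + 14 acquisitions,
  i.e. 20 evaluations versus the grid's 26.  Near-duplicate proposals
  (within 5e−4 of a visited point) are suppressed.

**Common random numbers.**  Inner-fold sampler seeds are fixed per inner
fold, *not* per candidate ρ.  The objective is then a smooth function of ρ
(Monte-Carlo noise is shared across candidates), so argmins reflect genuine
differences between kernels rather than chain noise.  This is a deliberate
design choice for stable selection.

## Nested cross-validation

7 outer folds estimate generalization; 5 inner folds inside each
outer-training set select ρ without touching outer-test labels.  Folds
partition observation rows, stratified by environment (per-stratum sizes
differ by ≤ 1); a `by_line` switch holds out whole lines instead.  Inner
fits drop the outer-test rows entirely and mask only the validation cells;
the outer refit uses the full table with the test cells masked.  One fold
plan is shared by all strategies so relative-efficiency comparisons are
paired.  Every inner evaluation's cell-level predictions are logged;
`verify_inner_objective` recomputes each fold's objective and argmin from
that log alone, an after-the-fact audit that the selected ρ used no
outer-test information.

## Metrics

NRMSE = RMSE / |mean(observed)| per trait per fold (the absolute value keeps
the metric nonnegative for negative-mean traits; for the positive-valued
traits this model targets it is the plain mean).  Trait-level values average
folds; the across-trait summary averages traits; standard errors are
sd/√(folds).  "Global" rows pool all test cells across environments before
normalizing — with heterogeneous environment means the pooled mean is larger
and Global NRMSE sits below every per-environment value, which matches how
multi-environment summaries of this kind behave; a `mean_of_env` alternative
averages per-environment NRMSEs instead.  Relative efficiency is
NRMSE_ref/NRMSE_alt (RE > 1 ⇔ the alternative predicts better): re_grs =
NT/GrS, re_bo = NT/BO, re_grs_bo = GrS/BO.

## Synthetic data

The generator draws allele frequencies uniform in a MAF band (default
0.05–0.5, mirroring common QC), genotype codes Binomial(2, f_j) — or
Binomial(1, f_j) for presence/absence panels — and phenotypes exactly from
the model above at a known ρ_true, returning every draw for recovery
studies.  Residual scale is set after the genetic terms are realized so the
per-trait genetic fraction of variance is `signal_fraction` (default 0.6, a
moderately heritable trait).  Presets reproduce the shapes of five published
breeding datasets (lines/environments/traits/markers/balance), including
per-environment line counts and a one-environment-per-line layout.

What the generator does *not* emulate: linkage disequilibrium, population
structure, family relatedness, selection, or real trait architectures.
Lines are exchangeable draws, so pairwise marker distances concentrate
around their mean (relative spread ≈ 1/√p).  Consequences: (i) kernels at
different bandwidths are nearly affine transforms of one another, so the
inner objective is much flatter in ρ than on real panels whose structured
distances spread widely — bandwidth-recovery studies on these data are
intrinsically weakly identified, and passing or failing them bounds what can
be said about real data; (ii) prediction accuracies are more uniform across
folds than in real trials.

## Validation studies (scripts/acceptance.py)

Problem sizes are the package's desk-scale choices:

* **BLUP oracle** — single trait, fixed Σ_T and R, identity kernel, J = 15
  lines × 2 environments (n = 30), 20 000 retained draws, compared to
  Henderson's mixed-model equations.
* **Σ_T recovery** — J = 200, I = 3, nT = 2, ρ_true = 0.5; the posterior
  mean is averaged over 8 replicate datasets before comparison.  A single
  replicate is dominated by the Wishart noise of the realized genetic draw
  (sd ≈ 0.1 per element at J = 200) plus posterior spread; replication
  measures the estimator, not one draw.
* **ρ recovery** — J = 150, p = 300, nT = 2, ρ_true = 0.9, Σ_TgE = Σ_T,
  signal fraction 0.6; one outer fold of a fresh 7×5 plan per replicate,
  10 replicates, tuning chains of 200 iterations (80 burn-in), refits of
  600 (200).  Reports how often grid search selects the grid point nearest
  0.9 and the mean RE versus no tuning.  Under this generator the selection
  is weakly identified (see above), and the hit rate reflects that.
* **BO convergence** — (ρ−0.6)² with the 20-evaluation budget, 10 seeds.
* **Leakage audit** — a small grid-search run whose selected ρ is recomputed
  from the inner prediction log.

## Known limitations

* REML/frequentist fitting is out of scope; so are trait-specific kernels
  and environmental covariates.
* The GE trait covariance is estimated from effectively one replicate per
  cell; it is identified only through kernel correlations among lines within
  an environment and is the least precise component.
* Unbalanced layouts forgo the diagonal fast path for the line-effect
  update (a dense J-dimensional Cholesky per trait per sweep); J of a few
  hundred remains comfortable on one core.
* The sampler assumes post-QC, imputed markers; there is no missing-genotype
  handling.
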