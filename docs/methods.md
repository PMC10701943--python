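# Methods

## Normal-model corrector (`pycombat_norm`)

### Model and estimation

Expression of gene *g* in sample *j* of batch *i*:

```
y_gij = α_g + X_j β_g + γ_gi + δ_gi ε_gij,   ε_gij ~ N(0, 1).
```

The design matrix has one indicator column per batch (no global
intercept) followed by numeric covariate columns; γ is identified by
the constraint Σ_i (n_i/N) γ_gi = 0, with α_g defined as the
batch-size-weighted average of the per-gene batch coefficients.

Estimation proceeds in four steps.

1. **Standardization.** Per-gene least squares on the full design. The
   pooled variance σ̂²_g is the mean squared residual with denominator
   N (the non-missing sample count when values are missing); the
   standardized data are z = (y − α̂ − Xβ̂)/σ̂. Per-batch estimates on
   the z-scale are γ̂_gi (batch means of z) and δ̂²_gi (within-batch
   variances, denominator n_i − 1).
2. **Hyperpriors.** Across genes and per batch, γ̂ is moment-matched to
   a normal prior (mean γ̄_i, variance τ²_i, denominator G − 1) and
   δ̂² to an inverse-gamma prior with shape λ_i = (m² + 2s²)/s² and
   scale θ_i = (m s² + m³)/s², where (m, s²) are the across-gene mean
   and variance of δ̂².
3. **Shrinkage.** *Parametric*: per gene and batch, iterate

   ```
   γ*  = (n τ² γ̂ + δ²* γ̄) / (n τ² + δ²*)
   δ²* = (θ + ½ Σ_j (z_j − γ*)²) / (n/2 + λ − 1)
   ```

   from (γ̂, δ̂²) until the larger relative change drops below `tol`
   (default 1e-4, cap 1000 iterations; genes converge independently
   and per-gene iteration counts are returned). *Non-parametric*: gene
   g's posterior in batch i is the average of every other gene's
   (γ̂, δ̂²) weighted by the likelihood of g's z-values under
   N(γ̂_g', δ̂²_g'); weights are accumulated in log space with max
   subtraction, and a gene whose weights all underflow keeps its own
   estimates (with a warning).
4. **Adjustment.** y* = (σ̂/δ*)(z − γ*) + α̂ + Xβ̂.

### Special modes and degenerate inputs

- **Reference batch**: α̂ is the reference batch's own coefficient and
  σ̂² is pooled over the reference batch's residuals only, so the
  batch-free scale is the reference scale; reference samples are
  returned bit-identical.
- **Mean-only**: δ²* ≡ 1 and the location posterior is the closed form
  γ* = (τ² γ̂ + γ̄)/(τ² + 1) — the conditional posterior mean at unit
  variance and unit effective sample size, with no fixed-point
  iteration. This reproduces the behavior of the established R
  implementation of the algorithm exactly; a batch with a single
  sample is legal in this mode only, because its variance never enters
  the adjustment.
- Genes constant across all samples (σ̂² = 0) bypass correction and
  are returned unchanged with a warning; missing values are ignored in
  all per-batch moments and stay missing in the output.
- If the across-gene variance of δ̂² is zero the inverse-gamma prior is
  unidentified; variance shrinkage is skipped (δ²* = δ̂²) and location
  shrinkage still applies.
- Gene–batch cells whose posterior is exactly the identity transform
  (γ* = 0, δ²* = 1), and only those, are passed through untouched, so
  a no-op posterior reproduces the input bit for bit rather than to
  rounding error.

The corrector is fully deterministic given the input order; the batch
order (hence parameter-table column order) is the labels'
first-appearance order.

### Verification against the reference implementation

On a 12 × 10 toy fixture (3 batches, one covariate; frozen under
`tests/data/`) the corrected matrices agree with the standard R
implementation (`sva::ComBat`) to ≤ 4e-6 in all parametric modes
(plain, covariate, reference-batch) — residual differences reflect the
convergence tolerance — and to machine precision (≤ 1e-12) in the
non-parametric and mean-only modes, which are iteration-free.

## Count-model corrector (`pycombat_seq`)

### Model and estimation

Counts follow y_gij ~ NB(μ_gij, φ_gi) with Var = μ + φμ² and

```
log μ_gij = α_g + X_j β_g + γ_gi + offset_j,
```

offsets being log raw column sums (no normalization factors — users
who want TMM-style scaling can pre-scale, and this choice is
documented precisely so they can).

- **Dispersions** are estimated per batch by maximizing the Cox–Reid
  adjusted profile likelihood (NB log-likelihood at the IRLS-fitted
  coefficients minus ½ log det X'WX, W = μ/(1 + φμ)) over
  φ ∈ [1e-6, 10]: a batch-common value by a 9-point log grid plus
  golden-section refinement of the summed APL, then per-gene
  refinement (vectorized golden section, brackets seeded by the common
  value and a method-of-moments candidate max(0, (v − m)/m²)) when the
  batch has more than (covariate columns + 2) samples. A batch whose
  profile likelihood peaks at the lower bound is treated as Poisson
  (φ = 0) with a warning.
- **GLM fitting** is per-gene IRLS with log link and fixed dispersion
  (each sample uses its batch's gene-wise value), initialized at
  per-indicator-column means of log((y + 0.1)/library), converged when
  the deviance change falls below 1e-8 (relative to max(1, |deviance|))
  or 100 iterations; linear predictors are clipped to ±30 so all-zero
  batches stay finite. Divergent genes fall back to method-of-moments
  coefficients (log batch means net of the mean offset) with a warning.
- **Quantile matching.** The batch-free target distribution keeps the
  covariate and offset terms but replaces the batch coefficient with
  the batch-size-weighted average α_g = Σ_i (n_i/N) coef_gi and pools
  the dispersion the same way (with a reference batch, both come from
  the reference batch instead). Each entry y is mapped as: y ≤ 1
  passes through; p = CDF(y − 1) under the batch NB; |p − 1| < 1e-4
  passes through (the discrete quantile is meaningless that deep in
  the tail); otherwise the output is 1 + Q(p) under the batch-free NB,
  where Q(p) is the smallest integer k with CDF(k) ≥ p. These edge
  rules make the map the exact identity when the two distributions
  coincide, and they are bit-identical to the R reference helper on a
  shared fixture (frozen under `tests/data/mq_*.tsv`). Dispersions
  below 1e-8 use the Poisson CDF/quantile (1/φ would overflow).

Genes with all-zero counts everywhere bypass the fit and return
unchanged; genes that are all-zero within a single batch are still
fitted. Output is an integer matrix with the input's ids and dtype.
The pipeline has no randomness and is bit-reproducible.

On jointly simulated data the full pipeline reproduces the R reference
implementation's adjusted counts bit-exactly for ~97% of entries; the
remainder trace to the dispersion estimator, which the reference tool
delegates to a different package (edgeR-style APL with its own grid)
and which no published description pins down — gene-level dispersion
parity is therefore not a design goal; simulation-based recovery is.

## Synthetic data

`simulate_microarray` draws forward from the normal model: baselines
α_g ~ N(8, 2) (log2-intensity scale), batch shifts γ_gi ~
N(0, gamma_spread²) recentered to the weighted-zero constraint,
variance factors δ²_gi ~ inverse-gamma(delta_shape, delta_shape − 1)
(mean 1; delta_shape 4 gives across-gene variance 0.5, a moderately
heterogeneous scale effect). Defaults — 1000 genes, two batches of 20,
gamma_spread 1 — put the batch shift on the same footing as the unit
residual noise, a regime where correction is both necessary and
identifiable.

`simulate_counts` draws NB counts with log-normal base means (median
50, sdlog 1 — a realistic bulk RNA-Seq abundance spread), a designated
fraction (default 50%) of genes carrying a mean fold change in every
batch after the first (default 2×), uniform per-sample library factors
(default 0.7–1.4), and a common dispersion (default 0.3, typical of
bulk data). An optional balanced binary covariate multiplies a random
half of the genes by exp(beta_true) to test covariate preservation.

Both generators are driven by a single `numpy` Generator per call, so
a seed fixes the dataset bit-for-bit. They deliberately omit gene–gene
correlation, platform-specific noise, and outlier samples: passing
tests show the estimators recover the model's own structure, not that
real data satisfy the model.

## Diagnostics

`relative_difference_summary` reports the mean, empirical 2.5/97.5
percentiles and relative squared error Σ(a−b)²/Σb² of entry-wise
relative differences (entries with b = 0 are excluded and counted).
The interval is percentile-based rather than a normal approximation —
the differences between two correction variants are typically
heavy-tailed. `batch_f_statistics` is the per-gene one-way ANOVA F for
batch (df k − 1, N − k), +inf for genes with zero within-batch
variance.

## Known limitations and calibration notes

- Per-gene location correction removes the *observed* batch mean
  difference, not the true one, so post-correction two-sample batch
  tests are strongly conservative: on simulated data the rejection
  fraction at α = 0.05 drops from ~0.66 to ~0 (not to the nominal
  0.05). The R reference implementation behaves identically. Batch F
  statistics likewise fall well below their null median. This is a
  property of the algorithm family, worth knowing before interpreting
  post-correction inference.
- The count corrector requires ≥ 2 samples per batch; the normal
  corrector allows singleton batches only in mean-only mode.
- Quantile matching leaves counts 0 and 1 and deep-tail counts
  unchanged by rule; heavy batch effects on genes dominated by such
  counts are under-corrected.
- The acceptance script and tests use problem sizes of 1000–2000 genes
  and 12–40 samples — sizes at which every estimator is comfortably in
  its asymptotic regime while the whole suite stays quick to run.
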