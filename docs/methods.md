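# Methods

`tiscmr` identifies genes whose expression causally influences an
individual-level phenotype, using single-cell RNA-seq cohorts in which each
cell carries a pseudotime position on a differentiation trajectory. The
pipeline has four stages: (1) per-gene, per-individual **time-cumulative
expression offsets** estimated by sparse functional PCA (the PACE
conditional-expectation algorithm); (2) **sc-eQTL mapping** of those offsets
(and of several alternative per-individual summaries) against genotype
dosages; (3) **instrument selection** by FDR thresholding and greedy LD
clumping; (4) **one-sample Mendelian randomization** per gene, treating the
cumulative offset as the exposure, with 2SLS (quantitative outcomes) or
two-stage residual inclusion (binary outcomes) and an optional lasso on
direct instrument effects to absorb horizontal pleiotropy. A simulator of
population-scale dynamic single-cell transcriptomes with known causal
structure drives all evaluation.

## Time-cumulative offsets (PACE)

Each individual contributes a sparse, irregular series of normalized
expression values along pseudotime. Modelling the series as

    x_ij = mu(t_ij) + sum_k xi_ik phi_k(t_ij) + eps_ij,     eps ~ (0, sigma^2)

the components are estimated as in the PACE literature:

- **Mean** `mu(t)`: weighted local linear smoothing of the pooled
  observations (Epanechnikov kernel); bandwidth by generalized
  cross-validation (GCV) over a geometric grid.
- **Covariance** `R(s,t)`: local linear smoothing of the off-diagonal raw
  covariances `(x_ij - mu(t_ij))(x_il - mu(t_il))`, `j != l`, symmetrized;
  its own GCV bandwidth. Raw pairs are first collapsed onto the lattice of
  unique time-point pairs (weighted by multiplicity), which makes the
  product-kernel smoother a set of separable matrix products — cost scales
  with distinct time points, not cells.
- **Error variance** `sigma^2`: the smoothed squared-residual diagonal
  minus `R(t,t)`, averaged over the central 50% of the grid and floored at
  zero. The diagonal smoother gets its own GCV bandwidth; the variance
  curve is typically much rougher than the mean, and reusing the mean
  bandwidth was found to inflate `sigma^2` substantially.
- **Eigenpairs**: trapezoid-weighted discretization `W^(1/2) R W^(1/2)`,
  symmetric eigendecomposition, negative eigenvalues truncated. Signs are
  fixed so each eigenfunction integrates to a nonnegative value (first
  nonzero grid value positive on ties), making offset signs reproducible.
- **Number of components** `K`: the smallest `K` whose cumulative fraction
  of variance explained reaches the threshold (default 0.99).
- **Scores**: conditional expectation
  `xi_ik = lambda_k phi_ik' Sigma_Xi^{-1} (X_i - mu_i)` with
  `Sigma_Xi = Phi_i Lambda Phi_i' + sigma^2 I` reconstructed from the
  positive eigenpairs. The raw smoothed surface is indefinite and using it
  directly makes the solve explode for occasional individuals; the
  positive-part reconstruction is both the textbook form and numerically
  stable. Inversion uses the Woodbury identity (low-rank plus diagonal)
  with an unconditional relative ridge of `1e-8` times the mean eigenvalue
  added to `sigma^2` — negligible in regular fits and exactly the
  stabilizer needed when `sigma^2 = 0` (noiseless data).

The **time-cumulative offset** is
`xtilde_i = integral (xhat_i(t) - mu(t)) dt = sum_k xi_ik * integral phi_k`,
computed by composite trapezoid on the evaluation grid (101 points by
default). Both the score-linearity form and direct integration of the
reconstruction are implemented and agree to numerical precision; the test
suite asserts the identity at 1e-10.

### Normalization and interval aggregation

Counts are library-size scaled (each cell to the median total, `log1p`)
and z-scored per gene; zero-variance genes are excluded. Cells are then
averaged within equal-width pseudotime intervals per individual before
PACE, with the interval midpoint as the time stamp.

The default is **6 intervals per pseudotime unit** (capped at 150; 120
bins for a length-20 trajectory). Unit-width bins — the coarsest reading
of "rounding the pseudotime points" — were evaluated and rejected: with
~5 cells per unit bin the within-interval averaging discards enough
temporal signal that the cumulative offset becomes a slightly *worse*
readout of the per-individual genetic effect than the plain cell average,
erasing the very contrast the method exists for. At 6 bins per unit the
offsets match per-cell accuracy under complete sampling and clearly beat
the plain average under uneven sampling, while every smoothing input
stays on a small lattice. `n_intervals` is configurable everywhere.

## sc-eQTL mapping

Five strategies build per-sample design tables from the same data:

| strategy   | sample unit                  | response                      | covariates |
|------------|------------------------------|-------------------------------|-----------|
| `avg_eqtl` | individual                   | mean normalized expression    | —         |
| `cum_eqtl` | individual                   | PACE cumulative offset        | —         |
| `agg_eqtl` | (individual, interval)       | interval mean ("pseudo-individual") | —   |
| `dyn_eqtl` | (individual, interval)       | interval mean                 | midpoint pseudotime |
| `int_eqtl` | (individual, interval)       | interval mean                 | pseudotime; the reported test is the genotype x pseudotime interaction |

Every SNP-gene pair is tested by OLS with a two-sided t test. The engine
works on cross-product matrices (one `(samples x SNPs)' (samples x genes)`
product per design column), so a full 2 000-SNP x 50-gene scan is a few
matrix multiplications; it is verified coefficient-for-coefficient against
`statsmodels` OLS. Pseudo-individual strategies refuse individual-level
covariates (an individual's genotype is constant across its rows, so such
covariates are collinear by construction). Benjamini-Hochberg adjustment is
applied across all tests of a run; significant SNPs (default FDR < 0.05,
or a raw-p rule for cis-instrument selection on annotated data) are clumped
greedily per gene — keep the most significant, drop SNPs with dosage
`r^2 > 0.1` to a kept SNP, repeat. Per-SNP first-stage F statistics
(squared t) are recorded and instruments with F < 10 are flagged, not
dropped.

The pseudo-individual strategies are retained deliberately as negative
controls: splitting one individual's cells across rows leaves
within-individual correlation in the residuals, which inflates the
genotype test (the dramatic QQ lift the evaluation reproduces), while the
interaction contrast — a within-individual covariate — is conservative,
detecting essentially nothing.

## One-sample MR

For gene *g* with clumped instruments `Z` (taken from the `cum_eqtl` scan,
for the average-based estimators too) and exposure either the cumulative
offset (`pace_*`) or the per-individual mean (`avg_*`):

- **2SLS** (`*_linear`): stage 1 regresses exposure on `[1, Z]`; stage 2
  regresses the outcome on the fitted exposure. Inference by the
  heteroskedasticity-robust IV sandwich with HC1 small-sample scaling,
  which accounts for the generated regressor. Binary outcomes may be run
  through 2SLS directly for testing purposes.
- **2SRI** (`*_logit`): stage-1 residuals join the observed exposure in a
  second-stage logistic regression (Newton/IRLS, with a small-ridge
  fallback and a flag under separation). Standard errors follow the
  two-stage M-estimator sandwich that stacks the OLS normal equations and
  the logistic score (the Terza construction); it is validated against a
  nonparametric bootstrap.
- **Lasso pleiotropy control** (`*_lasso`): the second stage gains direct
  instrument effects `Z pi` under an L1 penalty on `pi` alone — the causal
  coefficient, intercept, and residual-inclusion term are never
  penalized (penalizing the causal effect would bias it). The penalty is
  chosen by 10-fold cross-validation (folds outcome-stratified for binary
  phenotypes; both stages re-fit per fold; MSE or deviance loss). In the
  linear case the unpenalized block is profiled out analytically, which
  also absorbs the exact collinearity of the fitted exposure with the
  instrument span; the remaining problem is a plain lasso solved by
  coordinate descent on the Gram matrix. The logistic case wraps penalized
  coordinate descent in IRLS. Point estimates come from a post-selection
  refit with the corresponding robust sandwich; with fewer than two
  instruments the estimator falls back to the plain fit (flagged).
  Optionally, individuals are resampled with replacement (both stages
  re-run at the chosen penalty; default 999 resamples when requested) for
  a percentile confidence interval and a CI-inversion p-value.

Genes are ranked by BH-adjusted p across genes; adjusted p <= 0.05 flags a
putative causal gene. When a bootstrap was run its p-value is used for
ranking, otherwise the robust Wald p. The evaluation pipelines run with
the bootstrap off and therefore rank on the Wald p: a B-resample bootstrap
p has granularity 2/(B+1), and at the benchmark scale (50 genes under BH)
any B that fits a desk-scale runtime forces every adjusted p above the
threshold, reading as zero power for reasons that have nothing to do with
the estimator.

## The simulator

The generator mirrors population-scale dynamic single-cell designs:

- Genotypes: independent biallelic dosages `Binomial(2, pi)`,
  `pi ~ U(0.05, 0.95)` (bounds keep loci polymorphic; configurable).
- Expression programs: `K = 10` reflected Gaussian random walks on a
  201-point grid (start 1.0, step sd 0.1), nonnegative loadings
  `h ~ Gamma(1/K, 1)`, gene scales `log phi ~ N(0.8, 1)`; the per-gene
  mean curve is `mu_g(t) = phi_g sum_k w_k(t) h_kg`.
- eQTL effects: each gene is regulated by 15-25 SNPs with base effects
  `delta ~ Gamma(3.6, 1/12)`, either constant or `sqrt(2) delta |sin t|`;
  the realized individual effect is Gaussian around the dosage-weighted
  sum (sd 0.1, one time-constant draw per individual-gene), entering
  multiplicatively: `mu_ng(t) = mu_g(t)(1 + lambda_ng(t))`, clipped at 0.
- Cells: 80-140 per individual; pseudotimes uniform on `[0, 20]`
  (complete) or from a per-individual 5-component Gaussian mixture with
  means `U(0, T)` and variances `U(0.5, 2.5)`, truncated by resampling
  (uneven). The mixture is drawn per individual: each donor is captured at
  its own set of trajectory stages, which is what makes plain
  per-individual averages noisy and gives the cumulative offset its
  advantage. Counts are negative binomial with mean `s_nm mu_ng(t)`
  (`log s ~ N(0, log(0.7)^2)`) and variance `alpha_g m^2 + beta_g m`
  (`log alpha ~ N(log 0.4, log(2)^2)`, `log beta ~ N(log 2, log(2)^2)`),
  with a Poisson fallback where the quadratic variance does not exceed the
  mean.
- Phenotypes: 20 of 100 genes (10 of 50 at desk scale) are causal with
  `gamma ~ N(0.5, 0.05)` (sd reading of the dispersion), effect curves
  constant (Y1), `cos t` (Y2), windowed (Y3), or windowed-cosine (Y4);
  100 SNPs are horizontally pleiotropic with `theta ~ N(0.5, 0.05)`; a
  standard normal confounder affects the outcome only. The linear
  predictor integrates `mu_ng(t) gamma_g(t)` by trapezoid over the grid.
  Quantitative outcomes add Gaussian noise with sd equal to the
  predictor's sd (signal explains ~50% of variance). Binary outcomes
  center the predictor *and standardize it to sd 2.0* before the inverse
  logit: the integrated-expression predictor has sd in the hundreds, so
  centering alone would give success probabilities of exactly 0 or 1 —
  deterministic, separable outcomes no logistic stage can fit. The sd-2
  rescaling keeps prevalence near 0.5 and probabilities in (0.02, 0.98)
  while preserving the ranking of individuals exactly.

What the generator does **not** emulate: branching (tree) trajectories
(the two linearly arranged segments share one scalar axis), linkage
disequilibrium between loci, batch effects, doublets, ambient RNA, or
pseudotime-inference error (pseudotime is treated as observed; in real
data it is itself an estimate). Passing benchmarks therefore demonstrate
the method's behavior under correctly ordered cells and independent loci,
not robustness to trajectory misestimation or LD; with real genotypes,
clumping proxies and population structure will lower precision in ways
these simulations cannot show.

## Evaluation

`run_pipeline` simulates, analyzes, and scores one dataset; `run_experiment`
repeats scenarios over independently seeded replicates (splittable seed
sequences; every random stage funnels through one generator per run) and
aggregates means with standard errors. Scoring: a discovery is a SNP-gene
pair at BH-adjusted p below threshold; precision (true discovery rate) is
NA when nothing is discovered; gene-level FDR uses `false / max(1, flags)`.
QQ diagnostics report sorted `-log10` p against uniform quantiles and the
genomic inflation factor (median observed over median theoretical 1-df
chi-square). The benchmark grid runs at desk scale — 200 individuals,
2 000 SNPs, 50 genes, 10 causal, 50 pleiotropic SNPs, 10 replicates per
scenario (50 smaller replicates for the error-control battery) — chosen so
the full evaluation completes in minutes on one core; the full-scale
design remains the `SimConfig` default.

## Numerical choices and degenerate inputs

- Local smoothers fall back from local linear to local constant to
  nearest-neighbor as the windowed design degenerates; bandwidth
  candidates span twice the median spacing to half the range.
- Eigenvalues below `1e-10 lambda_1` are truncated; a fit with no
  variation returns zero scores rather than failing.
- `Sigma_Xi` components cover 99.99% of positive variance (at most 50).
- Zero-variance dosages yield NA association rows, flagged; zero-variance
  genes are excluded at normalization with a warning.
- CV lambda grids run geometrically from just above the smallest
  all-zero-pi penalty down three decades; a boundary selection is flagged.
- Bootstrap p-values use the add-one rule `2(min(#<=0, #>=0)+1)/(B+1)`.
- All containers are deterministic functions of the configuration seed;
  identical seeds reproduce byte-identical datasets, fits, folds, and
  resamples.
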