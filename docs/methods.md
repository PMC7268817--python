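# Methods

## The model

`ihtglm` fits sparse multiple regression to genome-wide genotype data.
All SNPs enter a single generalized linear model: the response `y_i`
follows an exponential-family distribution with mean
`mu_i = g(x_i' beta + z_i' gamma)`, where `x_i` holds the standardized
minor-allele counts of sample `i`, `z_i` its non-genetic covariates,
and `g` the inverse link. Supported families are normal (identity
link), Bernoulli (logit), Poisson (log), negative binomial (log link
with a fixed number of required failures `r`, default 10, so the
variance is `mu + mu^2/r`), and, for completeness, gamma and inverse
Gaussian; the last two carry no simulation coverage here and should be
treated as experimental.

Sparsity is enforced by a hard constraint `||beta||_0 <= k` rather than
a shrinkage penalty. The maximizer is sought by projected gradient
ascent — iterative hard thresholding (IHT):

1. ascend: `beta + s * grad L(beta)` with `grad L = X' W1 (y - mu)`;
2. project onto the constraint set (see below);
3. if the loglikelihood did not increase, halve `s` up to 5 times;
   if all halvings fail, the last halved proposal is accepted anyway
   and the iteration continues (the `max_iter` cap, default 200,
   bounds the total work).

Convergence is declared when
`||b_next - b_prev||_inf / (||b_prev||_inf + 1) < tol` (default 1e-4);
the `+1` guards against division by zero at the all-zero model.
Because nothing shrinks surviving coefficients, effect estimates for
detectable SNPs are unbiased — the practical advantage over lasso-type
selection, whose penalty both shrinks estimates and, by leaving
residual signal on the table, invites false positives.

## Step size

The curvature-matched step for a GLM ascent direction `v` is
`s = ||v||^2 / (v' J v)` with the expected information
`J = X' W2 X`. Both diagonal weight matrices come from the family:
`W1 = g'(eta)/var(y)`, `W2 = g'(eta)^2/var(y)`.

Two variants are implemented.  `step_size(..., mask=None)` uses the
full gradient; for a Gaussian model this is the exact minimizer of the
quadratic objective along the gradient (the line-search oracle test
checks this). The solver itself uses the *normalized* variant: the
quotient is evaluated on the gradient restricted to the active support
(on the first iteration, to the support that projecting the gradient
selects). The restricted step is the exact one-dimensional maximizer
within the subspace the iterate actually moves in after projection, and
it is substantially larger than the full-gradient step, whose
denominator is inflated by curvature in thousands of coordinates the
projection will immediately zero out.  Empirically the difference is
not cosmetic: on the comparison-design problems the full-gradient step
stalls in fixed points that miss detectable causal SNPs (and needs an
order of magnitude more iterations), while the normalized step reaches
better optima in ~10 iterations and reproduces the reference
true/false-positive rates. The restricted quadratic form also needs
only a support-sized matrix product, so each iteration performs a
single full pass over the genotype matrix (the gradient).

## Projections

* **Top-k** — keep the `k` largest-magnitude coefficients. Exact zeros
  never enter the support.
* **Doubly sparse** — with SNPs partitioned into groups, keep the
  `lambda_g` largest magnitudes inside each group, rank groups by the
  retained squared norm `||P_g(beta_g)||^2`, and keep the top `j`
  groups. Ranking by retained mass makes the output a Euclidean-nearest
  point of the constraint set (verified against exhaustive enumeration);
  ranking by the *discarded* mass `||beta_g||^2 - ||P_g(beta_g)||^2`
  would select the groups least worth keeping and is not a projection.
  With one group and `lambda = k` this reduces exactly to top-k.
* **Prior-weighted** — the support is that of the projected Hadamard
  product `w * beta` (any positive weights); surviving coefficients
  keep their unweighted values. The built-in MAF scheme
  `w_j = 1/sqrt(2 p_j (1-p_j))` up-weights rare variants.

Ties are deterministic everywhere: equal magnitudes resolve to the
lowest coefficient index, equal group scores to the lowest group label.
Covariate coefficients (including the intercept) compete in plain-k
projection by default; `project_covariates=False` exempts them, and a
grouped constraint defined over SNPs only passes them through.

Optional **debiasing** replaces the coefficients on the current support
by the unpenalized GLM fit restricted to those columns (Fisher scoring,
tolerance 1e-8, at most 100 inner iterations; a singular restricted
design falls back to the unbiased iterate with a warning). It is off by
default and in every simulation harness; all reference results
reproduce without it.

## Genotype storage and implicit standardization

Genotypes live in PLINK's 2-bit SNP-major encoding (magic `6C 1B 01`;
codes 00→2, 10→1, 11→0, 01→missing, counting the minor allele), i.e.
`ceil(n/4)` bytes per SNP — a 32:1 saving over float64. Missing
genotypes are imputed with the per-SNP modal count (ties to the lower
count) before any numeric work. If a SNP's counted allele turns out to
be the major one, the labeling is flipped so counts are minor-allele
counts.

Standardization substitutes `(x - 2 p_j)/sqrt(2 p_j (1 - p_j))` with
`p_j` the estimated minor-allele frequency — the binomial
mean/variance, not the empirical column moments, so standardized
columns are mean-zero only in expectation. The standardized matrix is
never materialized: forward products decode only the support columns,
and transpose products stream over all SNPs, folding the centering in
as a rank-one correction and the scaling as a diagonal. Monomorphic
SNPs get scale zero — their standardized column is identically zero and
can never be selected (a warning is raised on file input).

Two computational backends sit behind the same interface:

* `packed` (default): streams over the 2-bit codes in column blocks,
  exact float64 arithmetic, `O(n + p)` working memory beyond the codes.
* `dense`: a float32 cache of the raw counts (integers, hence exact in
  float32) routed through BLAS; accumulation is single precision, so it
  agrees with the packed path to ~1e-6 relative. The experiment
  harness uses this backend for wall-clock reasons; every correctness
  test runs the packed path against dense float64 oracles at 1e-10.

Cross-validation restricts samples by index while keeping full-data
standardization; products on a fold are computed on zero-padded
full-length vectors, so no row copy of the genotype matrix is made.

## Cross-validation

`cv_iht` assigns samples to `q` folds uniformly at random (sizes differ
by at most one, reproducible from the seed), fits every sparsity level
in the path on each training complement, and scores the held-out fold
by the sum of squared deviance residuals — for the normal family, `n`
times the holdout mean squared error. The selected `k_hat` minimizes
the fold-averaged deviance; ties go to the smallest `k` (parsimony).
Each (fold, k) task is a pure function of the data and seed, so results
are identical under any execution schedule — the parallel contract.
A Bernoulli training fold with a single response class is skipped from
the average with a warning.

## The simulator

The generator reproduces the study conditions under which the reference
results were obtained; its defaults are those conditions.

* **Independent SNPs**: `maf_j ~ Uniform(0, 0.5)` (optionally floored,
  0.05 in the coefficient-recovery design, to avoid monomorphic columns),
  counts `Binomial(2, maf_j)` i.i.d. across samples.
* **LD blocks**: SNPs in blocks of 20. Each block carries a pool of 20
  binary haplotypes built by a two-state Markov chain (`x_1 ~
  Bernoulli(0.5)`, `x_{i+1} = x_i` with probability 0.75), the pool
  regenerated until both alleles appear at every SNP (an attempt cap of
  1000 guards the loop; at these parameters regeneration is rare). A
  sample's block genotype is the sum of two pool draws with
  replacement. Adjacent-SNP haplotype correlation is `2p - 1 = 0.5`
  before pool conditioning; correlation decays with separation within a
  block and vanishes across blocks. A trailing partial block is simply
  shorter.
* **Coefficients**: 10 causal SNPs with standardized effects
  0.1, 0.2, ..., 1.0 by default; the grouped layout places 1..5 causal
  SNPs in each of 5 blocks with effects drawn from {-0.2, +0.2}; the
  recovery design uses effects {0.5, 0.25, 0.10, 0.05} with allocation
  (3, 3, 2, 2) so every value has at least two SNPs.
* **Responses**: mean `g(clamp(eta))` with `eta` the *standardized*
  genotypes times the effect vector — effects are on the standardized
  scale, and simulation and fitting see exactly the same design.
  Normal responses have unit variance; negative binomial uses r = 10.

The clamp `eta in [-20, 20]` is applied to the linear predictor, in
simulation and fitting alike. It exists to stop `exp` overflow in the
Poisson/negative-binomial links (and logistic variance underflow); an
interval of ±20 only makes sense on the linear-predictor scale.

What the simulator does **not** emulate: population structure and
relatedness, genotyping error and informative missingness, real LD
(block-diagonal by construction, no long-range structure), dominance or
epistasis, and effect-size distributions tied to allele frequency.
Passing results therefore certify the estimator's behavior under a
correctly specified sparse GLM with idealized LD — not robustness to
confounding, which in real analyses is handled upstream (PCs as
covariates, kinship filtering).

## Harness problem sizes

The canonical designs run at: comparison (n=1000, p=10000, 3-fold CV
over k=1..50; 10 replicates in the acceptance run vs 50 in the
reference), coefficient recovery (n=5000, p=10000, fixed k=10, 30 vs
100 replicates), LD grouped (n=1000, p=10000, 30 vs 100), prior
weights (n=1000, p=10000, 30 replicates), and model-size recovery
(n=5000, 5-fold CV over k=1..20, p=10000 — reduced from 50000 — with
10 replicates). Replicate seeds are spawned from one root seed, so
every run is reproducible end to end.

## Numerical choices and degenerate inputs

* `k = 0` is a legal constraint: the fit returns the zero (or
  covariate-exempt) model immediately.
* A zero gradient (or zero/non-finite curvature quotient) signals
  convergence rather than dividing by zero.
* Deviance terms of the form `y log(y/mu)` are evaluated with
  `xlogy` so `0 log 0 = 0`; tiny negative deviances from floating
  cancellation are clamped to zero.
* Gamma and inverse-Gaussian linear predictors are additionally floored
  at 1e-8 (their inverse links require positive arguments).
* The float32 backend's products agree with the exact path to ~1e-6;
  all acceptance quantities are replicate averages, far above that
  noise floor.

## Known limitations

* `r` (negative binomial) and dispersions are fixed user parameters,
  never estimated.
* Groups must partition the SNPs; overlapping groups are unsupported.
* IHT solves a nonconvex problem: convergence is to a fixed point, not
  a certified global optimum. The normalized step and backtracking make
  stalls rare in the tested regimes, but pathological designs can still
  trap the iteration.
* The CLI loads the full BED payload into memory; out-of-core streaming
  is out of scope.
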