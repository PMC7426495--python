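# Methods

`mtgp` implements a two-stage genomic-prediction analysis for replicated
half-sib field trials of outcrossing crops (the motivating setting is
perennial-ryegrass breeding: families phenotyped for dry-matter yield and
visual growth score across locations and seasonal harvests, maternal
parents genotyped by low-depth genotyping-by-sequencing).  This note
documents the models, the estimator and sampler details, the synthetic
data generator and its limits, and the numerical choices.

## 1. Depth-aware genomic relationship matrix

GBS produces, per individual × SNP, a read depth `k` and a fractional
dosage `x = 2·alt/k ∈ [0, 2]` (`k = 0` ⇒ missing).  We model reads as
`alt ~ Binomial(k, g/2)` given the true dosage `g ∈ {0,1,2}`.

**Estimator ("KGD-style").**  With `p̂` the per-SNP mean dosage / 2:

* Off-diagonals: `K_ij = Σ_l (x_il − 2p_l)(x_jl − 2p_l) / Σ_l 2p_l(1−p_l)`,
  both sums over loci observed in *both* individuals (pairwise-complete,
  matched denominators, no imputation).  `E[x | g] = g`, so read noise
  cancels in expectation off the diagonal.
* Diagonal: the naive `Σ (x−2p)²` is inflated by the binomial sampling
  variance `x(2−x)/k`-style terms.  The per-locus correction
  `(x − 2p)² − x(2 − x)/(k − 1)` (loci with `k ≥ 2`) is exactly unbiased
  for `(g − 2p)²` under the binomial read model, so the corrected
  diagonal estimates the true-genotype VanRaden diagonal; at `k → ∞` the
  whole estimator reduces to plain VanRaden.

This is a documented stand-in in the spirit of depth-aware GRM software
for GBS data, derived from the stated read model rather than copied from
any implementation; its defining properties (diagonal unbiasedness at
depth 4, exact VanRaden reduction, invariance to locus duplication) are
tested.

**SNP filters.**  Order: missingness (≤ 50 %) → minor allele frequency
(≥ 5 %) → mean read depth (> 2, interpreted per SNP; a per-call reading
would interact with the missingness filter) → Hardy–Weinberg
disequilibrium `D > −0.05`.  Removal counts per filter are logged so the
choice is auditable.

**Hardy–Weinberg disequilibrium at low depth.**  A true heterozygote at
depth `k` is only *detected* as heterozygous (both alleles read) with
probability `1 − 2^(1−k)`; a naive heterozygote fraction is therefore
deflated even at depth ~10, which would push `D` below the −0.05
threshold for perfectly good SNPs.  We count a call heterozygous when
`0 < x < 2`, restrict to calls with `k ≥ 2`, and divide the count by the
summed detection probabilities `Σ (1 − 2^(1−k))`.  This makes `D`
approximately unbiased at any depth and reduces to the plain fraction at
high depth.  Note that pooling differentiated populations produces a
*genuine* heterozygote deficit (Wahlund effect) of roughly
`−F_ST · 2p(1−p)`; with five populations at `F_ST = 0.1` many SNPs sit
near the −0.05 threshold, which is a property of the data, not the
estimator.

**MDS.**  Classical principal coordinates on
`d²_ij = K_ii + K_jj − 2K_ij`; axis signs are fixed by making each
axis's largest-magnitude loading positive, so plots reproduce exactly.

## 2. Stage 1: plot-level mixed model

For one trait, a plot record decomposes as

    y = mu + g_i + s_m + (gs)_im + (gm)_in + p_o + b_onml + r_onmlj
        + c_onmlk + eps

with fixed location, measure and population effects (and a fixed class
per repeated check entry, which is excluded from the family BLUP output)
and random family `g`, family×location `gs`, family×measure `gm`,
replicate, row and column effects plus residual.  The family term may be
genomic, `g ~ N(0, K σ²_g)`; all other random terms are i.i.d.  Terms
whose factor collapses to one level (e.g. `gm` in a single-measure
analysis) are dropped automatically — an interaction with a single-level
factor is confounded with the family main effect.

**REML.**  Average-information REML on Henderson's mixed-model
equations:

* The coefficient matrix `C` (fixed + all random effects, the family
  block carrying `K⁻¹λ`) is dense-factorized by Cholesky; its inverse
  (LAPACK `dpotri`) supplies every trace the EM update and the REML
  score need, and the score/AI identities
  `tr(P V_i) = (q_i − λ_i tr(A_i⁻¹C^{ii}))/σ_i²`,
  `y'P V_i P y = û_i'A_i⁻¹û_i / σ_i⁴` avoid forming `P` (both were
  verified against a brute-force dense-`V` implementation; the restricted
  likelihood identity is also unit-tested).
* AI steps are clipped at the lower bound `1e-8 × var(y)`; components
  pinned at the bound with negative gradient leave the AI system; step
  halving guards against likelihood decreases; a full EM sweep is the
  fallback (EM never leaves the parameter space).  Convergence:
  `|Δ logL| < 1e-8` or relative parameter change `< 1e-6`, max 200
  iterations; non-convergence is flagged, not raised.
* Aliased fixed-effect columns are dropped by pivoted QR; a singular
  coefficient matrix receives a logged ridge of `1e-8 ×` its mean
  diagonal.  Standard errors come from the inverse AI matrix.

**Genomic heritability** of family means:
`h²_g = σ²_g / (σ²_g + σ²_gs/s + σ²_gm/m + σ²_ε/(s·m·b))`, with `s, m, b`
the design counts of the fitted data (locations, measures contributing
to the trait, replicates).  Missing interaction terms contribute zero.

**Genetic correlation proxy.**  The Pearson correlation of
independently fitted family BLUPs over shared families.  Because each
trait's BLUP carries its own prediction error, this correlation
attenuates towards `r_g · sqrt(h²_x · h²_y)` when plot errors are
independent across traits; with traits scored on the same plots
(correlated residuals) it sits higher.  The parameter-recovery tests
assert against the derived attenuated value, not against `r_g` itself.

## 3. Stage 2: genomic prediction

The stage-2 response is the stage-1 family BLUP (no reliability
weighting — none is defined for the two-stage pipeline).

**Single trait.**  `y = 1β + α + ε`, `α ~ N(0, K σ²_u)`.
`GBLUP` fits the variance ratio by a one-dimensional REML profile in the
eigenbasis of `K` and returns `E[α | y]` for *all* individuals in `K`,
observed or not.  `RKHSRegression` is the Bayesian twin (kernel = `K`):
flat prior on `β`, scaled-inverse-χ² priors (df 5, mode `0.5 var(y)` —
the conventional even prior split of the phenotypic variance) on both
variances, Gibbs-sampled in the eigenbasis so one sweep is O(n) after a
single O(n³) eigendecomposition.  Default chain 3000 iterations / 1500
burn-in, thinning 1 (lengthen for final runs).  With a linear kernel the
two are the same model; their agreement (GEBV correlation > 0.99 across
datasets) is an acceptance property.

**Bivariate.**  `(α₁; α₂) ~ N(0, G₀ ⊗ K)`, residuals `N(0, I ⊗ R₀)` with
`G₀` unstructured (2×2) and `R₀` diagonal (an unstructured-R variant is
deliberately not offered by default).  Gibbs cycle: (1) data
augmentation of missing cells, (2) trait means, (3) breeding values in
the eigenbasis of `K` — per eigencomponent a 2×2 conditional, vectorized,
(4) `G₀` from its inverse-Wishart conditional (df `t+3`, prior mean
`diag(0.5 var(y_t))`), (5) `R₀` diagonals from scaled-inverse-χ²
conditionals using *observed* cells only, so imputation cannot bias the
residual variance.  Missing-cell augmentation keeps every conditional
conjugate under arbitrary masks, which is what the trait-assisted CV2 /
CV3 masks require.  Traits are processed internally in sorted-label
order and mapped back, making trait relabelling/swapping an exact
symmetry of the output.  When no individual has both traits observed
(CV3-like masks) the genetic covariance is identified through
relatedness alone; the fit flags fewer than 10 complete rows in its
diagnostics.

**Identifiability and prior sensitivity of the genetic correlation.**
After marginalizing the breeding values, the data carry far fewer
effective observations about `G₀` than `n`: the information lives in the
spread of the kernel's eigenvalues and shrinks with the response
reliability.  Validating the sampler against an independent
Metropolis–Hastings run on the marginalized likelihood (identical
priors) and against a direct MLE confirmed the chains target the exact
posterior — and that at response reliabilities of 0.5/0.35 the posterior
mean of `r_g` sits ~0.1–0.15 below a true value of 0.9 under the default
priors, while aggressively weakening the inverse-Wishart scale
concentrates the prior near the zero matrix and biases mid-range
correlations upward instead.  There is no prior that is neutral at these
signal levels.  In practice the stage-2 responses are multi-harvest
family BLUPs with reliabilities nearer 0.7–0.8, where the posterior mean
recovers `r_g` across the whole range under the default priors; the
parameter-recovery tests run at those reliabilities.  Reported `r_g`
values at low reliability should be read as conservative.

**Exact oracle.**  `conditional_mean_bv` assembles the joint MVN of all
breeding values and observed cells at fixed `(G₀, R₀)`, profiles the
trait means by GLS, and conditions exactly (capped at n = 500).  It is
the finite-sample reference for the sampler and the cleanest explanation
of why CV2/CV3 help: a test individual's secondary phenotype enters the
conditioning set and carries primary-trait information proportional to
the genetic covariance.

## 4. Evaluation harness

* **Schemes.**  ST-CV1 (primary in training only), MT-CV1 (both traits
  in training only), MT-CV2 (secondary also observed in the test set),
  MT-CV3 (secondary in the test set only).  Default 70/30 split, 100
  iterations, splits unstratified by population (a stratified option
  exists, off by default).  Iteration `i` uses seed `base_seed + i` for
  split and sampler, so equal base seeds give identical split sequences
  — scheme comparisons are paired, which is also how percent
  improvements `100·(r̄_MT − r̄_ST)/r̄_ST` are computed.
* **Metrics.**  Predictive ability `r_p` = Pearson correlation of
  test-set GEBVs with held-out BLUPs; bias = slope of observed-on-GEBV
  regression (1 = unbiased; > 1 = under-dispersed predictions — this
  convention makes "bias ≈ 1 ⇒ unbiased" read correctly).
* **Single-trait engine.**  The CV harness uses the closed-form REML
  GBLUP by default (exact, ~100× faster); the Gibbs RKHS engine is a
  flag away and their equivalence is separately enforced.
* **LOPO.**  One deterministic fold per population, trained on the
  rest; folds with fewer than 3 test (or training) families are skipped
  with a warning.
* **Training-size sweep.**  Per replicate the test set (20 %) is drawn
  first; nested training subsets are prefixes of one permutation of the
  remainder, so the curve within a replicate is nested.  Size fractions
  are proportions of the non-test pool, in (0, 1]; at fraction 1.0 the
  sweep coincides with a 80/20 Monte-Carlo CV.  The fitted model at each
  size sees only the training subset plus the test set.

## 5. Synthetic data generator

The generator emulates the training-population design end to end:

* **Population structure.**  Balding–Nichols: ancestral frequencies
  uniform on the MAF range, per-population frequencies
  `Beta(p(1−F)/F, (1−p)(1−F)/F)`.  The last two populations drift in two
  stages (F/2 each) through a shared intermediate, emulating a pair of
  breeding pools with common lineage — in MDS they are the nearest pair.
* **Read model.**  Depth `~ Poisson(mean_depth)`, zeroed with the extra
  missing rate; `alt ~ Binomial(depth, dosage/2)`.  A heterozygote at
  depth `k` is observed homozygous with probability `2^(1−k)` — the
  phenomenon both the GRM diagonal correction and the HW filter
  correction address.
* **Breeding values.**  `u ~ MVN(0, G₀ ⊗ K_true)` with `K_true` the
  VanRaden GRM of the true genotypes, i.e. the generative twin of the
  bivariate prediction model.
* **Trial.**  One plot per family × location × measure × replicate;
  fixed offsets drawn once from N(0,1) (magnitude irrelevant downstream,
  recorded for reproducibility); every random term i.i.d. normal at its
  configured variance; a fresh row-column grid per (location,
  replicate), row/column effects redrawn per measure.  Realized
  variances of all drawn effects are recorded — the sharpest
  single-seed oracle for REML recovery.
* **Defaults.**  Non-genetic variances default to ratios matching a
  multi-harvest yield trial (family×location ≈ 0.67 σ²g, family×measure
  ≈ 0.12 σ²g, residual ≈ 11.5 σ²g, replicate/row/column 0.25 σ²g —
  plot-level nuisance magnitudes are not published for such trials, so
  these are calibrated to give heritabilities in the reported 0.2–0.65
  band and are fully configurable).  `SimConfig.from_heritability`
  solves the residual variance so the implied `h²_g` hits a requested
  target exactly, zeroing interactions whose factor has a single level.
* **Seeding.**  One master seed; child streams (genotypes, reads,
  breeding values, trial) spawned in a fixed order, so each stage is
  replayable in isolation.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: linkage/LD between SNPs (markers are
independent), pedigree structure beyond population membership,
cross-trait residual correlation (traits scored on the same plot), G×E
beyond i.i.d. interaction terms, spatial autocorrelation beyond i.i.d.
row/column effects, selection, and the genotype-calling pipeline
upstream of dosages.

## 6. Problem sizes and numerical choices

* Parameter-recovery runs use 500 families, 2 locations, 1 measure,
  2 replicates, and the true-genotype kernel (GRM noise is tested
  separately); heritability estimates average 10 seeds per level.
  Scheme-ordering runs use 400 families over the five-population panel
  with 30 paired CV iterations.  The acceptance script runs the full
  463-family pipeline with 100 ST / 30 MT iterations.  These sizes were
  chosen to put Monte-Carlo error comfortably inside the asserted
  tolerances.
* Kernels are bent (smallest eigenvalue raised to 1e-8) before
  factorization wherever positive definiteness is required; bends are
  logged.
* The Gibbs samplers are deterministic given a seed; two runs with the
  same seed agree bit for bit.  The `effective sample size` reported for
  scalar chains uses the initial-positive-sequence estimator.
* Infinite-depth statements are limits: at depth `k` the dosage noise is
  O(k^-1/2) and the diagonal correction O(1/k); tests use depth 1e12
  against a 1e-10 tolerance.

## 7. Known limitations

* Stage 1 is single-trait; cross-trait information enters only in stage
  2, and the BLUP-correlation genetic-correlation proxy inherits the
  attenuation described above.
* The bivariate model is exactly two traits; a t-trait extension is a
  design possibility but untested and not exposed.
* The MT sampler's bias diagnostic (observed-on-GEBV slope) can exceed 1
  under trait-assisted masks; it is reported, not corrected.
* REML cost is dominated by the dense inverse of the mixed-model
  coefficient matrix (O((p+q)³) per iteration); trials far larger than
  ~10⁴ plots with dense kernels would need a sparse-inverse
  implementation.
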