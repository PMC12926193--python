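# Methods

## The sc-PME model

For one peak, per-cell fragment counts are modeled as

    y_i ~ Poisson(mu_i)
    log mu_i = log s_i + beta g_{d(i)} + x_i' gamma + a_{d(i)} + b_{l(i)}
    a_d ~ N(0, sigma_a^2),  b_l ~ N(0, sigma_b^2)

where `s_i` is the cell's library size (offset), `g` the donor's alt-allele
dosage in [0, 2], `x_i` fixed covariates, and `a`/`b` donor and library
random intercepts. Assumptions worth stating explicitly:

- **Conditional Poisson.** Given the random effects, counts are Poisson.
  Donor- and library-level overdispersion is absorbed by the intercepts;
  *cell-level* overdispersion (e.g., residual state variation not captured by
  the covariates) is not modeled. On data that violate this, Wald p-values
  will be anticonservative — the permutation calibration below exists to
  measure exactly this.
- **Random intercepts only.** No random genotype slopes; genotype effects are
  assumed homogeneous across donors within a cell type (cell-state
  heterogeneity is modeled explicitly via the dynamic interaction test
  instead).
- **Covariates.** TSS enrichment, mitochondrial fraction, log10 fragment
  count, plus optional genotype PCs (`compute_genotype_pcs`) and latent
  embedding dimensions (`compute_lsi`), all z-scaled within the analyzed cell
  subset. Constant columns are rejected rather than silently dropped.

### Estimation

Both fitting modes solve the penalized IRLS (PIRLS) system jointly for
`(beta, u)` at given variance components; the mixed-model equations are
assembled with per-factor `bincount` reductions and solved densely (the
random-effect dimension is tens of donors + a few libraries, so dense
Cholesky is exact and fast).

- `laplace` (default for single fits): Nelder-Mead over `log sigma`
  maximizing the Laplace-approximate marginal log-likelihood
  `l = log f(y|u_hat) - u_hat' D^-1 u_hat / 2 - log det(D Z'WZ + I) / 2`.
- `pql` (fast mode, default for scans): EM-type updates
  `sigma_f^2 <- mean_d(u_d^2 + Var(u_d|y))`, a handful of outer iterations.
  This mirrors the common zero-adaptive-quadrature GLMM setting used for
  large scans.

During development the Laplace mode was checked against an independent
reference GLMM implementation on a 4,000-cell instance and agreed to ~1e-5
in coefficients, standard errors, and variance components.

Numerical choices: PIRLS steps larger than 8 on the linear-predictor scale
are damped (keeps `exp` in range); convergence is declared on a 1e-10
linear-predictor change *or* a penalized-log-likelihood plateau (the latter
handles logistic separation, where coefficients drift while the likelihood
is flat); variance components are floored at 1e-4 and flagged when pinned;
non-convergence yields a flagged record with missing p, never a silent
value.

### Scans, leads, significance

SNPs within ±125 kb of the peak center (closed interval) with minor-allele
dosage sum ≥ 4 are tested. Within a scan, variance components are estimated
once per peak on the genotype-free base model and held fixed across that
peak's SNPs — with a single added covariate the components barely move, and
this makes a 600-peak × 10-SNP scan run in about a minute. Per peak,
p-values are Bonferroni-corrected by the number of SNPs actually tested
(counted after the minor-allele filter), the smallest-p SNP becomes the lead
(ties break by distance to peak center, then lexicographic SNP id), and
Storey q-values across lead `p_bonf` call significance at q < 0.1. The
q-value guard refuses fewer than 50 peaks unless lowered explicitly.

Storey's pi0 uses the lambda grid 0.05..0.95 (step 0.05) with a cubic
smoothing spline evaluated at the largest lambda, clipped to (0, 1]; below
20 p-values it falls back to pi0 = 1 (plain BH) with a warning.

### Dynamic caQTLs

The interaction test adds `theta * t_i + delta * g_i * t_i` to the mean
(`t` = topic loading) and compares against the reduced model without
`delta` by a 1-df LRT on the Laplace log-likelihood. A constant loading
makes `delta` unidentifiable and is reported as stat 0 with a flag. The LRT
is invariant to affine rescaling of `t` because the main effects absorb
location and scale. q-values are computed per topic (within cell type) and
multiplied by the number of topics tested for the SNP (capped at 1);
significance is adjusted q < 0.01. The shipped cell-type-to-topic map
(`DEFAULT_TOPIC_MAP`) lists the topics present in each common immune cell
type.

## Topic model

Poisson NMF `X ~ Poisson(L F')` fit by multiplicative EM updates (monotone
in the objective; asserted to 1e-8 per step) followed by cyclic
coordinate-descent refinement: per topic column, a single Newton step on
the exact 1-D objective, vectorized across cells (or peaks), with the
nonzero-entry mean vector maintained incrementally. A refinement sweep that
would decrease the objective (Newton overshoot) is reverted and replaced by
one EM step, so the full schedule never ends below its initialization. The
exact coordinate-descent variant is asserted through objective monotonicity,
not iterate identity.

Larger models are fit incrementally: columns of `1/K_new` (loadings) and
`1/n_peaks` (factors) are appended to a smaller fit and the schedule rerun
(EM main phase, then two consecutive refinement runs), which keeps topic
`i`'s identity stable across the K ladder. Conversion to the multinomial
model uses `u_k = sum_j F_jk`, `Phi = F/u`, `Q proportional to L u`.
Projection of new cells solves the per-cell convex Poisson problem with `F`
fixed (EM on L only); all-zero cells get uniform loadings with a warning.

Peak "score" means the multinomial column `Phi[:, k]` throughout (top-peak
selection, gene scores); the alternative — the raw factor column — differs
only by the per-topic scale `u_k` and would select identical peak sets.
Gene scores sum body-overlapping peak scores plus `w(d) = exp(-d/5000)`
weighted scores of peaks whose centers lie within 5 kb upstream of the TSS
(strand-aware); the kernel is configurable (`exp` | `power`), defaulting to
the exponential because that matches the gene-activity weighting scheme the
score design follows. Gene Z-scores standardize across topics with the
sample SD. Technical topics are flagged at |Spearman rho| > 0.3 against any
QC covariate — the threshold is a package choice, exposed as a parameter.

## Trajectories

A trajectory is the rank-percentile transform of one topic's (optionally
reversed) loading, scaled to [0, 100] over defined cells (mask ∩ loading ≥
`min_loading`); undefined cells are NaN. Rank scaling (vs min–max) makes
the trajectory invariant to any strictly monotone transform of loadings.
Quintiles partition defined cells with stable-sort tie assignment. The
differential-activity contrast takes all first-quintile cells as control and
case cells of quintiles 2..5 as the test group (Wilcoxon rank-sum + BH; the
test choice follows the wrapped single-cell toolchain's default).

The topic–phenotype association fits mixed logistic models
`logit(case) ~ loading + MTratio + nFrags + (1|donor)` vs the null without
the loading (cells with loading ≤ 0.01 removed; covariates z-scaled;
`nFrags` is log10 unique fragments). Because case status is constant within
donor, the donor intercept can saturate the likelihood and the LRT is
*conservative* under the null — the test suite asserts it is never
anticonservative, and power is realistic only when loadings separate case
and control donors strongly. This is a property of the model itself, not of
the implementation, and was confirmed against a reference mixed-model
implementation during development.

## Meta-analysis

Fixed effects: inverse-variance. RE2: the profile likelihood in
`(mu, tau^2)` is maximized over a 50-point log-spaced tau² grid (including
0) spanning [1e-8, 100·max se²] plus safeguarded 1-D Newton refinement;
`S = 2(l_max − l(0,0))`, `p = ½P(chi2_1 > S) + ½P(chi2_2 > S)`. The
asymptotic mixture is anti-conservative for very few studies (the original
method tabulates small-sample nulls); tests therefore validate S against a
brute-force 2-D grid oracle and calibration by simulation, not small-sample
p-values. `S >= z_FE^2` always, since the tau² = 0 slice contains the FE
solution.

## Colocalization and integration

Per-SNP Wakefield log-ABFs (`labf = ½[log(1−r) + r z²]`, `r = W/(W+se²)`)
with prior variance W = 0.15² (quantitative) or 0.2² (case–control) — the
conventional defaults of the ABF framework. The five hypothesis sums are
accumulated in log space; H3's distinct-pair subtraction is done with
`log1p(-exp(...))` and clipped (with a warning) if numerically non-positive.
Eligibility requires >150 shared SNPs including both traits' lead SNPs.
The PP4 threshold for calling a locus colocalized defaults to 0.75 and is
always explicit in outputs, since no single community value exists.

GWAS loci: greedily take the global min-p SNP below 1e-7, carve a ±0.5 Mb
locus window, remove all SNPs within ±1 Mb of the lead, repeat. Both radii
are parameters because "within 1 Mb" phrasing is ambiguous between them.

Sharing: a peak significant in a focal type (q < 0.1) is shared with
another type iff that type's q < 0.1/(n_types − 1) = 0.025 at five types —
a Bonferroni correction over the other types; context count = 1 + number of
other types passing. Pairwise pi1 applies Storey's estimator to the second
type's p-values at peaks significant in the first.

Co-accessibility uses 100 random cell aggregates (a simple stand-in for
k-NN metacells, which are out of scope): Pearson r of per-aggregate mean
accessibility, co-accessible at r > 0.5 within 125 kb, distance-matched
controls from 0.05 < r < 0.1. Note the null SE of r at 100 aggregates is
~0.1, so the control band sits inside the null noise — matched controls are
"not co-accessible" rather than "anti-correlated". Distal tests refit the
sc-PME model of the reference lead SNP against each co-accessible peak's
counts, with Storey q across pairs at q < 0.1.

Fisher enrichment uses the exact conditional (hypergeometric) test with the
conditional-MLE odds ratio and 95% CI.

## The synthetic-data generator

The generator plants known structure in a multi-donor, multi-library,
sparse Poisson count matrix:

    log mu_ic = log(s_i · 1e-4 · base_c) + log m_ic
                + beta_c g_d(i) + delta_c g_d(i) t_i + a_d(i) + b_l(i)

- `s_i`: lognormal library size, default exp(N(9.2, 0.5²)) ≈ 10⁴ fragments.
- `base_c`: per-peak baseline, uniform in (0.1, 1.0) mean fragments per peak
  per 10⁴ library size — the accessible-peak regime (strong peaks selected
  for QTL testing), giving per-cell-per-peak means well below saturation and
  ~50% zero entries at default depth.
- `m_ic`: topic modulation `sum_k l_ik phi_ck`, normalized per peak to mean
  1 across cells, with Dirichlet(0.5) loadings over 4 topics and sparse
  gamma-enriched peak profiles.
- Effects: half the peaks carry `beta ~ N(0, 0.5²)`; a fifth of those also
  carry an interaction `delta ~ N(0, 0.5²)` with the last topic's loading;
  donor and library intercept SDs 0.25 and 0.15 — log-scale magnitudes
  typical of donor and batch variation in accessibility data.
- Genotypes: per-SNP binomial(2, maf) marginals (maf uniform in
  (0.05, 0.5)) coupled by an AR(1) Gaussian copula on two latent haplotypes
  (adjacent-SNP rho 0.9); each peak gets an independent 10-SNP LD block
  within ±10 kb of its center, and peaks sit 300 kb apart so mapping windows
  never overlap.
- QC covariates (TSS enrichment, mitochondrial ratio) are drawn jointly
  normal with log depth at correlation 0.5, so covariate adjustment is
  exercised non-trivially; log10nFrags tracks depth with small noise.
- A single global seed drives everything through fixed offsets; identical
  config + seed gives bit-identical output.

What the generator does **not** emulate: fragment-level structure (Tn5 duplicates,
per-allele counts), doublets, batch effects beyond library intercepts,
peak-to-peak spatial correlation (except what topics induce), empirical LD
or allele-frequency spectra, and — deliberately — any *cell-level*
overdispersion beyond the Poisson mixture that the model itself assumes.

## What the permutation calibration shows (and does not)

`permute_and_calibrate` shuffles the donor-to-genotype assignment
(preserving within-donor LD), reruns the scan, and reports the fraction of
peaks with lead-SNP q < 0.1, separately for QTL-bearing peaks and for
sparsity/mean-matched control peaks. On the generator's exactly-Poisson
data the sc-PME test is well calibrated, and a calibrated test followed by
Bonferroni + Storey FDR control rejects a *near-zero* fraction of truly
null hypotheses — FDR controls the error rate among calls, not the
per-null rejection rate. Both reported fractions therefore land near 0%
here (small upward drift is possible for the QTL-bearing set, since a
random permutation of ~40 donors retains sample correlation ~0.16 with the
true genotypes and leaks a sliver of planted signal). A markedly larger
fraction on *real* data — where fragment counts are overdispersed relative
to Poisson — measures the model's anticonservativeness on that data, which
is precisely what the procedure is for; passing here demonstrates the
pipeline's statistical correctness, not that real-data p-values are clean.

## Problem sizes

Defaults throughout are desk-scale by design: the calibration analysis uses
600 peaks × ~4,000 cells × 40 donors (≈ 6,600 GLMM fits, about a minute in
PQL mode); calibration simulations in the test suite use 300–500 replicates
at 30 donors × 25–30 cells; topic-recovery tests use ~700 cells × 160
peaks. These sizes keep every statistical property assertable while the
full suite runs in a few minutes.

## Known limitations

- PQL-mode standard errors are conditional on the estimated variance
  components (as in standard GLMM software); no small-sample (Satterthwaite)
  correction.
- RE2 p-values use the asymptotic mixture (see above).
- The mixed-logistic topic–phenotype LRT is conservative for donor-constant
  phenotypes (see Trajectories).
- Colocalization assumes a single causal variant per trait per region; no
  LD-aware or multi-causal extension.
- The co-accessibility aggregate scheme is random grouping, not
  nearest-neighbor metacells.
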