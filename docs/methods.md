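# Methods

## The model

`funsig` estimates, for every SNP, a prior probability that the variant
is trait associated *given only its functional annotations*, and then
combines that prior with the evidence in case-control genotype data.

Write `A_s = 1` when SNP *s* is associated with the phenotype, `F_s` for
its standardized annotation row, and `pi_s = Pr(A_s = 1 | F_s)`.  The
annotation model is logistic:

    logit(pi_sb) = alpha + F_sb . beta

Training data are matched pairs of LD blocks: a *case* block is a known
associated SNP plus its LD partners (pairwise R² ≥ 0.8), a *control*
block is a matched unassociated SNP plus its partners.  Which SNP in a
case block is the truly functional one is unknown, so the latent
indicators are marginalised under two assumptions — a case block
contains **at least one** associated SNP, a control block **none** — and
conditional independence of blocks and of SNPs within blocks given the
annotations.  Each case block then contributes
`log(1 - prod_s (1 - pi_sb))` and each control block
`sum_s log(1 - pi_sb)` to the log likelihood.  For one block the case and
control probabilities are complementary; both are computed through
`log1mexp(sum log(1 - pi))` so that blocks full of near-zero or near-one
probabilities do not underflow.

**Intercept prior.** With 1,675 case seeds among 48,888 training SNPs,
at least 1,675 associated variants are expected: `logit(1675/48888) =
-3.34`.  If 10% (20%) of case blocks hold a second associated SNP the
value moves to -3.24 (-3.15).  The intercept prior is therefore
Normal(-3.24, 0.1), consistent with fewer than 2,178 (= 1.3 × 1,675,
rounded up) associated variants.

**Coefficient priors.** Either independent standard normals, or the
normal-exponential-gamma (NEG) shrinkage prior
`beta | v ~ N(0, v)`, `v ~ Exp(psi)`, `psi ~ Gamma(shape, scale =
1/scale_neg²)`, whose marginal closed form is evaluated through the
confluent hypergeometric function `U` (equivalently a parabolic
cylinder function).  The NEG behaves like soft thresholding: under a
normal likelihood with variance `v`, the posterior mode is exactly zero
while the MLE sits inside a threshold neighbourhood.  Because the NEG
penalty is non-convex, the *global* mode can jump away from zero
slightly before the local-slope threshold `v × sqrt(2) Γ(λ+1)/(γ Γ(λ+½))`
is reached; `neg_threshold_halfwidth` therefore finds the exact switch
point by bisection (the local formula remains available as
`method="local"`).  Calibration follows the a-priori rule: parameters
should keep more than 10% of 57 coefficients outside the threshold
region with probability at most 0.10; `calibration_report` checks this
by Monte Carlo against the chosen likelihood variance (which the data
analyst must supply — it is a property of the intended fit, not of the
prior).

## Posterior sampling

Single-parameter random-walk Metropolis in a systematic scan (alpha,
beta_1, …, beta_m), chains started from prior draws.  The full protocol
is 10 chains × 50,000 post-burn-in iterations thinned by 1,000 — 500
retained coefficient vectors.  Per-parameter proposal steps adapt
during burn-in and are frozen afterwards; the target band for
parameter-level acceptance is 0.3–0.5.  The adaptation rule is
Robbins-Monro on the log step toward 40% acceptance (the band
midpoint), in windows of 50 iterations with a decaying gain.  A
band-edge rule (multiply step when acceptance leaves the band) was
rejected because it parks parameters arbitrarily close to 0.3 or 0.5,
where sampling noise takes the measured rate outside the band.

The likelihood hot path caches the per-SNP linear predictors in
float32 and fuses each proposal into one vector pass (about 0.25 ms per
parameter update at 42,000 SNPs); predictors are refreshed in float64
every 500 sweeps, bounding accumulated rounding drift.  The float32
path perturbs the sampled target by ~1e-5 in log density, far below
Monte-Carlo error; the float64 `block_loglik` is the reference the
kernel is tested against (1e-9 against brute-force enumeration).

Convergence is monitored with the Gelman-Rubin potential scale
reduction factor across chains.

**Desk preset.** Tests and worked examples use a reduced protocol:
2 chains × 1,200 post-burn-in iterations, thin 12, burn-in 800 (200
retained draws).  This preset was sized so the whole verification suite
runs on a single CPU in minutes; all statistical checks (prior
recovery, parameter recovery, held-out concordance) are run under it.

## Combining with association data

For SNP *s* with log Bayes factor `log BF_s` in favour of association,

    Pr(A_s = 1 | D, X, G_s, F_s)  ~=  mean_i expit(alpha_i + F_s.beta_i + log BF_s)

over retained draws i.  The fixed-prior comparator uses
`expit(logit(p0) + log BF_s)` with `p0 = 1e-5`; its ranking is invariant
to `p0`.

Bayes factors come from Laplace approximations to the marginal
likelihoods of two Bayesian logistic regressions (covariates vs
covariates + dosage), with N(0, 10²) priors on covariate coefficients
and intercept and N(0, 0.25²) on the dosage coefficient (most reported
GWAS log-odds ratios are below 0.5).  Dosages are deliberately left
unstandardized so the 0.25 prior speaks the per-allele log-odds scale.
Monomorphic SNPs are flagged and given log BF 0 rather than aborting a
genome-wide run.  With only summary statistics, Wakefield's ABF
`0.5 log(V/(V+W)) + z²W/(2(V+W))` is the fallback; natural logs are
used throughout.

## Evaluation

* `followup_summary`: mean/median ranks of labelled true-positive /
  true-negative sets under both analyses and counts inside follow-up
  budgets (5,000 and 10,000 by default).
* `concordance_index`: fraction of held-out matched pairs whose case
  block has the larger mean `Pr(A|F)`; ties count one half (the
  standard c-index convention); 95% interval by seeded percentile
  bootstrap over pairs (2,000 resamples).
* `adjacent_signature_correlation`: Pearson correlation of the
  signatures of adjacent SNP pairs within 2.5%-quantile distance bins
  (40 bins), located at bin-midpoint distances, plus the distance CDF.
* `variance_decomposition`: per-annotation-class variance of
  `F[:, class] @ beta_mean` over a reference SNP set, normalised by the
  sum of class variances (cross-class covariance ignored, so fractions
  sum to one by construction).

Ranks are descending with min-rank ties, which keeps golden-file
comparisons deterministic.

## Annotation features

Binned signal summaries yield `log(mean)`, `log(mean/sd)` and
`log(max)` per bin; a zero bin sum is set to one before the mean, the
SD uses the sample (n-1) denominator, and any non-positive argument to
a log (zero SD included) falls back to 0 — the same "absent signal is
coded 0" convention the cluster tracks use.  Natural logs are used for
all of these.  Conservation ranges assign mean/sd per range to the SNPs
inside it; SNPs in no range get 0 (the training mean after
standardization) with a missing flag.  Scored interval tracks are
summarised per SNP as (count, mean log score) or (indicator,
log score), 0 outside every cluster.  Function classes and RegulomeDB
categories become reference-coded indicator blocks ('unknown' and
category 7 are the baselines).  High-dimensional signal classes are
reduced by correlation PCA keeping the smallest component count
explaining ≥ 90% of variance, with the sign convention that each
component's largest-magnitude loading is positive (determinism across
BLAS implementations).

MAF enters through a four-column natural cubic spline with boundary
knots at 0.05 and 0.5 and three interior knots at training-MAF
quartiles.  (A natural spline with two interior knots spans only three
non-constant functions, so exactly four columns require three interior
knots — the df = 4 convention of standard spline software.)

Standardization statistics (column means/SDs) are always taken from the
training assembly and stored; scoring re-applies them unchanged, so
signatures transport across studies.

## Study design operations

Control matching is sequential: cases in a seeded random permutation,
each matched uniformly at random among frame SNPs with the same
chromosome, platform label and MAF bin (MAF/0.02 rounded half-to-even),
excluding frame SNPs in any tabulated LD (R² > 0) with a case and
candidates whose LD block would intersect a case block or an already
chosen control block.  Absent LD-table pairs count as R² = 0.  Seed
deduplication keeps one uniform representative per connected component
of the block-overlap graph.

## Synthetic data

`simulate_blocks` draws block sizes uniformly on 1–20, generates
correlated features (single latent factor, default pairwise correlation
0.3, ~20% binary columns), standardizes them by their known population
moments (so planted coefficients live on the same scale the model
fits), draws `A_s ~ Bernoulli(expit(alpha + F_s.beta))` independently,
and accepts candidate blocks as case/control by the presence of an
associated SNP until both quotas fill.  Defaults: alpha = -3.34, 57
features, 5 nonzero coefficients of magnitude 0.5.

`simulate_casecontrol` draws Hardy-Weinberg genotypes, logistic disease
risk (population rate 10% at the genotype mean), and stratifies until
the case and control quotas fill — the retrospective design the Bayes
factor model assumes.

What the generator does *not* emulate: LD between SNPs within a block
(features are independent across SNPs given the factor), annotation
classes with realistic marginal distributions, genotyping platform
ascertainment, or population structure.  Passing recovery and
discrimination checks on this generator therefore demonstrates
correctness of the inference machinery under the model's own
assumptions, not performance on real annotation databases.

## Problem sizes used in verification

The verification suite scales the real protocol down to desk size as a
package design choice: parameter recovery uses 2,000 synthetic matched
pairs with 57 features under the desk preset; discrimination uses 550
pairs (300 training / 250 held out) with planted |beta| = 1.0 signal
and a matched null run; Laplace-vs-quadrature checks use n ≤ 50
datasets with ≤ 3 parameters (adaptive quadrature in 1-2 dimensions);
the ABF agreement panel uses 200 SNPs at n = 2,000 subjects.

## Known limitations

* The sampler is serial per chain; chains are not parallelised.
* `neg_logpdf` relies on `scipy.special.hyperu`; extremely small scales
  (gamma < 1e-4) have not been validated.
* The concordance bootstrap resamples pairs only; it ignores
  Monte-Carlo error in the posterior draws themselves.
* Interval overlap uses an interval tree per chromosome; tracks with
  millions of intervals would want a sorted-array implementation.
* The block likelihood treats LD blocks as conditionally independent;
  overlapping blocks violate this and are rejected upstream by the
  design code rather than modelled.

## Notes on optional inputs

Bins with zero total signal are recorded through the "sum set to one"
rule; a separate zero-signal indicator column is not emitted by
default, but `assemble_feature_matrix` accepts any extra indicator a
caller derives (`BinSummary.sum == 0`) alongside the roster columns.
The `annotate` command stores the fitted MAF-spline knots and any
retained PCA loadings in the statistics sidecar and reuses them in
scoring mode, so scored feature matrices are exactly transportable.
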