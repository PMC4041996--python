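# funsig — functional signatures of trait association

`funsig` implements a two-stage Bayesian framework for using functional
genomic annotations to improve the ranking of candidate variants in
genome-wide association studies (GWAS).

**Stage 1 — learn a functional signature.**  Known trait-associated
SNPs ("cases") and matched unassociated SNPs ("controls"), each grouped
with its LD partners (R² ≥ 0.8) into blocks, train a logistic model for
the latent per-SNP association indicator A_s:

    logit Pr(A_s = 1 | F_s) = α + F_s β

where F_s is the SNP's standardized annotation row (conservation
scores, histone-mark and RNA-seq principal components, TFBS/DNase
clusters, function class, RegulomeDB category, MAF spline, …).  Which
SNP inside a case block is truly functional is unknown, so case blocks
contribute `1 − Π_s (1 − π_s)` (at least one associated SNP) and
control blocks `Π_s (1 − π_s)` (none) to the likelihood.  The intercept
prior is N(−3.24, 0.1²), derived from the expected count of associated
variants in the training frame; coefficients take either N(0, 1) or
normal-exponential-gamma (NEG) shrinkage priors, and the posterior is
sampled by per-parameter random-walk Metropolis.  `F_s β` is the SNP's
*functional signature*; `LO_F = α + F_s β` is its prior log-odds of
association.

**Stage 2 — combine with association data.**  For each SNP a Bayes
factor BF_s compares Bayesian logistic regressions of disease status
with and without the genotype dosage (Laplace-approximate marginal
likelihoods; or Wakefield's ABF from summary statistics).  Posterior
probabilities average over the stage-1 draws:

    Pr(A_s = 1 | data) ≈ mean_i expit(α_i + F_s β_i + log BF_s)

Ranking by this quantity ("Rank_A+F") is compared against ranking by
the Bayes factors alone under a fixed 10⁻⁵ prior ("Rank_A").

The package also provides the surrounding machinery: annotation feature
extraction from bin summaries / BED tracks / categorical labels,
matched case-control block design construction, the concordance-index
evaluation over held-out block pairs, follow-up budget summaries,
adjacent-SNP signature correlation profiles, and a synthetic-data
generator that realises exactly the process the likelihood assumes.

## Worked example

Simulate a small study, train under the NEG prior, and evaluate
held-out concordance:

```sh
funsig simulate --pairs 200 --features 20 --seed 7 --outdir sim/
cat > run.yaml <<EOF
prior: {type: neg, shape: 0.978, scale: 0.0245}
sampler: {preset: desk, seed: 7}
EOF
funsig train --features sim/features.tsv --blocks sim/blocks.tsv \
             --config run.yaml --out draws.tsv --psrf-out psrf.tsv
funsig evaluate --features sim/features.tsv --blocks sim/blocks.tsv \
                --draws draws.tsv --out eval.json
```

which prints, for this seed:

```
wrote 400 blocks over 4516 SNPs to sim
retained 200 draws; wrote draws.tsv
concordance 0.5950 (95% CI 0.5250-0.6600) over 200 pairs
```

The concordance index is the fraction of matched case/control block
pairs in which the case block has the larger mean `Pr(A_s = 1 | F_s)`;
0.5 is chance.  Here the generator planted five coefficients of
magnitude 0.5 among twenty annotation columns, and the fitted
signatures separate the 200 block pairs with concordance 0.595 — a
modest but real signal, as expected when only a quarter of the columns
carry information.  (Pass `--n-train` to `funsig design`, or subset
pairs before `funsig evaluate`, to score held-out pairs instead of the
training pairs shown here.)  The same operations are available as
library calls (`funsig.simulate_blocks`, `funsig.sample_posterior`,
`funsig.concordance_index`, …).

For ranking, `funsig bf` (subject-level dosages) or `funsig abf`
(summary statistics) produce per-SNP log Bayes factors, and
`funsig combine` merges them with the draws into a scored table with
`lo_f`, `posterior_prob`, `rank_a` and `rank_af` columns.

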