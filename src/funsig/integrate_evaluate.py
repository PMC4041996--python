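"""Combine functional signatures with Bayes factors; rank and evaluate.

Given posterior draws (alpha_i, beta_i) of the signature model and a
per-SNP log Bayes factor, the posterior probability of association is
the Monte-Carlo average

    Pr(A_s = 1 | data)  ~=  mean_i expit(alpha_i + F_s . beta_i + log BF_s),

i.e. the prior log-odds from the functional data plus the evidence in
the genotype data, pushed through the inverse logit draw by draw.  The
fixed-prior alternative uses a single small prior probability for every
SNP; its ranking depends only on the Bayes factors.

Evaluation outputs mirror a GWAS follow-up workflow: rank tables under
both analyses, counts of known positives/negatives inside follow-up
budgets, the concordance index over matched held-out block pairs, the
distance profile of signature correlation for adjacent SNPs, and a
variance decomposition of the signature by annotation class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import rankdata

__all__ = [
    "prior_logodds",
    "posterior_prob",
    "fixed_prior_posterior",
    "rank_variants",
    "score_table",
    "EvaluationReport",
    "followup_summary",
    "concordance_index",
    "adjacent_signature_correlation",
    "variance_decomposition",
]


def prior_logodds(F, alpha, beta):
    """Prior log-odds of association, alpha + F . beta.

    ``F`` may be one annotation row or a matrix of rows; ``alpha`` and
    ``beta`` one draw or arrays of draws (an (n_snps, n_draws) matrix
    results in the latter case).
    """
    F = np.asarray(F, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if beta.ndim == 1:
        if F.shape[-1] != beta.shape[0]:
            raise ValueError("feature/coefficient dimension mismatch")
        return alpha + F @ beta
    if F.shape[-1] != beta.shape[1]:
        raise ValueError("feature/coefficient dimension mismatch")
    alpha = np.asarray(alpha, dtype=float)
    if F.ndim == 1:
        return alpha + F @ beta.T  # one SNP against all draws -> (n_draws,)
    return alpha[None, :] + F @ beta.T  # (n_snps, n_draws)


def posterior_prob(F, log_bf, draws):
    """Monte-Carlo posterior probability of association per SNP."""
    lo = prior_logodds(F, draws.alpha, draws.beta)
    if lo.ndim == 1:  # single SNP row against many draws
        return float(expit(lo + log_bf).mean())
    log_bf = np.broadcast_to(np.asarray(log_bf, dtype=float), (lo.shape[0],))
    return expit(lo + log_bf[:, None]).mean(axis=1)


def fixed_prior_posterior(log_bf, prior_prob: float = 1e-5):
    """Posterior probability under one fixed prior probability for all SNPs.

    ``expit(logit(prior_prob) + log BF)``.  Rankings by this quantity do
    not depend on the choice of ``prior_prob``.
    """
    if not 0.0 < prior_prob < 1.0:
        raise ValueError("prior_prob must lie in (0, 1)")
    log_bf = np.asarray(log_bf, dtype=float)
    out = expit(logit(prior_prob) + log_bf)
    return out if out.ndim else float(out)


def rank_variants(scores):
    """Ranks with 1 = best (largest score); ties share the minimum rank."""
    scores = np.asarray(scores, dtype=float)
    if np.any(np.isnan(scores)):
        raise ValueError("scores contain NaN")
    return rankdata(-scores, method="min").astype(int)


def score_table(F: pd.DataFrame, draws, bf: pd.Series) -> pd.DataFrame:
    """Per-SNP scores and ranks under both analyses.

    ``lo_f`` is the posterior-mean prior log-odds (the functional
    signature plus intercept), ``rank_a`` ranks by Bayes factor alone,
    ``rank_af`` by the Monte-Carlo posterior probability.
    """
    bf = bf.reindex(F.index)
    if bf.isna().any():
        raise ValueError("every SNP in F needs a log Bayes factor")
    lo = prior_logodds(F.to_numpy(), draws.alpha, draws.beta)
    post = expit(lo + bf.to_numpy()[:, None]).mean(axis=1)
    out = pd.DataFrame(
        {
            "lo_f": lo.mean(axis=1),
            "log_bf": bf.to_numpy(),
            "posterior_prob": post,
        },
        index=F.index,
    )
    out["rank_a"] = rank_variants(fixed_prior_posterior(out["log_bf"].to_numpy()))
    out["rank_af"] = rank_variants(out["posterior_prob"].to_numpy())
    return out


@dataclass
class EvaluationReport:
    """Follow-up budget counts and rank summaries for labelled SNP sets."""

    rank_summary: pd.DataFrame
    budget_counts: pd.DataFrame


def followup_summary(true_pos: pd.DataFrame, true_neg: pd.DataFrame, budgets=(5000, 10000)) -> EvaluationReport:
    """Summarise ranks of known positives and negatives under both analyses.

    Inputs need ``rank_a`` and ``rank_af`` columns (ranks without and
    with the functional signatures); any additional numeric columns
    (e.g. ``lo_f``, ``log_bf``, ``maf``) are carried into the mean and
    median summaries.  Budget counts report how many SNPs of each set
    rank inside each follow-up budget under each analysis.
    """
    sets = {"true_pos": true_pos, "true_neg": true_neg}
    for name, df in sets.items():
        if len(df) == 0:
            raise ValueError(f"{name} set is empty")
        if not {"rank_a", "rank_af"}.issubset(df.columns):
            raise ValueError(f"{name} set needs rank_a and rank_af columns")
    rows = []
    for name, df in sets.items():
        numeric = df.select_dtypes("number")
        for stat, fn in (("mean", np.mean), ("median", np.median)):
            row = {"set": name, "stat": stat}
            row.update({c: float(fn(numeric[c])) for c in numeric.columns})
            rows.append(row)
    rank_summary = pd.DataFrame(rows).set_index(["set", "stat"])
    counts = []
    for name, df in sets.items():
        for budget in budgets:
            counts.append(
                {
                    "set": name,
                    "budget": int(budget),
                    "n": len(df),
                    "within_rank_a": int((df["rank_a"] <= budget).sum()),
                    "within_rank_af": int((df["rank_af"] <= budget).sum()),
                }
            )
    return EvaluationReport(
        rank_summary=rank_summary,
        budget_counts=pd.DataFrame(counts).set_index(["set", "budget"]),
    )


def concordance_index(pairs, n_boot: int = 2000, seed: int = 0):
    """Concordance over matched block pairs, with a bootstrap interval.

    ``pairs`` is a sequence of (case-block probabilities, control-block
    probabilities).  A pair concords when the case block's mean
    probability exceeds the control block's; ties count one half.  The
    95% interval is a seeded percentile bootstrap over pairs.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs to evaluate")
    diffs = []
    for case_p, ctrl_p in pairs:
        case_p = np.asarray(case_p, dtype=float)
        ctrl_p = np.asarray(ctrl_p, dtype=float)
        if case_p.size == 0 or ctrl_p.size == 0:
            raise ValueError("each pair needs non-empty blocks")
        diffs.append(case_p.mean() - ctrl_p.mean())
    diffs = np.asarray(diffs)
    wins = (diffs > 0).astype(float) + 0.5 * (diffs == 0)
    ci = float(wins.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(len(diffs), size=(n_boot, len(diffs)))
    boot = wins[idx].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ci, (float(lo), float(hi))


def adjacent_signature_correlation(
    positions: pd.DataFrame, signatures, n_bins: int = 40
):
    """Signature correlation of adjacent SNP pairs, by distance quantile.

    Pairs are consecutive SNPs within a chromosome.  Pair distances are
    cut into ``n_bins`` quantile bins (2.5% increments by default); each
    bin reports the Pearson correlation between the two signatures of
    its pairs, located at the midpoint of the bin's distance range.
    Bins with fewer than three pairs are left NaN with a warning.
    Returns (correlation table, distance CDF table).
    """
    if not {"chrom", "pos"}.issubset(positions.columns):
        raise ValueError("positions frame needs 'chrom' and 'pos' columns")
    signatures = np.asarray(signatures, dtype=float)
    left, right, dist = [], [], []
    for _, idx in positions.groupby("chrom").groups.items():
        sub = positions.loc[idx].sort_values("pos")
        locs = positions.index.get_indexer(sub.index)
        if len(locs) < 2:
            continue
        p = sub["pos"].to_numpy()
        left.append(signatures[locs[:-1]])
        right.append(signatures[locs[1:]])
        dist.append(np.diff(p).astype(float))
    if not dist:
        raise ValueError("no adjacent pairs; need >= 2 SNPs on some chromosome")
    left = np.concatenate(left)
    right = np.concatenate(right)
    dist = np.concatenate(dist)

    edges = np.quantile(dist, np.linspace(0.0, 1.0, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = bins == b
        n = int(mask.sum())
        mid = 0.5 * (edges[b] + edges[b + 1])
        if n < 3:
            warnings.warn(f"distance bin {b} has {n} < 3 pairs; correlation omitted")
            r = np.nan
        else:
            x, y = left[mask], right[mask]
            if x.std() == 0.0 or y.std() == 0.0:
                warnings.warn(f"distance bin {b} has zero signature variance; omitted")
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"bin": b, "midpoint_distance": float(mid), "n_pairs": n, "pearson_r": r})
    corr = pd.DataFrame(rows).set_index("bin")
    order = np.sort(dist)
    cdf = pd.DataFrame(
        {"distance": order, "cdf": np.arange(1, len(order) + 1) / len(order)}
    )
    return corr, cdf


def variance_decomposition(
    F: pd.DataFrame, beta_mean: pd.Series, class_map: dict, ref_snps=None
) -> pd.Series:
    """Fraction of signature variance attributable to each annotation class.

    For class c the contribution of its columns is
    ``F[:, c] @ beta_mean[c]``; the reported fraction is that
    contribution's variance over the reference SNPs divided by the sum
    of the class variances (cross-class covariances are ignored, which
    is what makes the fractions sum to one).
    """
    ref = F if ref_snps is None else F.loc[ref_snps]
    variances = {}
    for cls, cols in class_map.items():
        cols = list(cols)
        if not cols:
            raise ValueError(f"annotation class {cls!r} has no columns")
        missing = [c for c in cols if c not in F.columns]
        if missing:
            raise ValueError(f"class {cls!r} refers to absent columns {missing}")
        contrib = ref[cols].to_numpy() @ beta_mean[cols].to_numpy()
        variances[cls] = float(np.var(contrib, ddof=1))
    total = sum(variances.values())
    if total == 0.0:
        raise ValueError("signature has zero variance over the reference SNPs")
    return pd.Series({c: v / total for c, v in variances.items()}, name="variance_fraction")
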