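"""Synthetic inputs for every stage of the pipeline.

The generator realises exactly the data-generating process the block
likelihood assumes: per-SNP latent association indicators drawn from a
logistic model on correlated annotation features, blocks labelled case
when they contain at least one associated SNP and control otherwise,
and retrospective case-control genotype data under a logistic disease
model with Hardy-Weinberg genotypes.

Defaults echo the scale of the real training design: a rare marginal
association rate (alpha = -3.34, about 3.4% of SNPs), 57 annotation
columns of which only a handful carry signal, and block sizes of 1-20
SNPs (a seed plus its LD partners).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .association_bf import SubjectData
from .study_design import Block

__all__ = [
    "SimulationConfig",
    "TruthBundle",
    "simulate_features",
    "make_true_beta",
    "simulate_blocks",
    "simulate_casecontrol",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic block design."""

    n_pairs: int = 2000
    m: int = 57
    block_size_range: tuple = (1, 20)
    correlation: float = 0.3
    binary_fraction: float = 0.2
    alpha: float = -3.34
    n_nonzero: int = 5
    beta_magnitude: float = 0.5
    seed: int = 0
    max_batches: int = 2000

    def __post_init__(self) -> None:
        if self.n_pairs <= 0 or self.m <= 0:
            raise ValueError("n_pairs and m must be positive")
        lo, hi = self.block_size_range
        if not (1 <= lo <= hi):
            raise ValueError("block sizes must satisfy 1 <= min <= max")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")
        if self.n_nonzero > self.m:
            raise ValueError("cannot plant more nonzero coefficients than features")


@dataclass
class TruthBundle:
    """Ground truth of a simulated design."""

    alpha: float
    beta: np.ndarray
    associated: pd.Series  # per-SNP 0/1 indicator
    labels: dict = field(default_factory=dict)  # block_id -> case/control


def _column_kinds(m: int, binary_fraction: float, rng: np.random.Generator):
    n_binary = int(round(binary_fraction * m))
    kinds = np.array(["continuous"] * m, dtype=object)
    if n_binary:
        kinds[rng.choice(m, size=n_binary, replace=False)] = "binary"
    return kinds


def simulate_features(
    n_snps: int,
    m: int,
    correlation: float,
    seed: int,
    binary_fraction: float = 0.2,
) -> pd.DataFrame:
    """Correlated raw annotation columns, ~20% of them binary.

    A single latent factor per SNP induces pairwise correlation
    ``correlation`` among the continuous columns; binary columns come
    from thresholding their latent at zero (so they are Bernoulli(1/2)
    before standardization).
    """
    if not 0.0 <= correlation < 1.0:
        raise ValueError("correlation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_snps, 1))
    eps = rng.standard_normal((n_snps, m))
    latent = np.sqrt(correlation) * g + np.sqrt(1.0 - correlation) * eps
    kinds = _column_kinds(m, binary_fraction, rng)
    cols = {}
    for j in range(m):
        name = f"f{j + 1}"
        cols[name] = (latent[:, j] > 0).astype(float) if kinds[j] == "binary" else latent[:, j]
    return pd.DataFrame(cols, index=[f"snp{i}" for i in range(n_snps)])


def _standardize_population(raw: pd.DataFrame) -> pd.DataFrame:
    """Standardize by the generator's population moments.

    Continuous columns are already standard normal; binary columns are
    Bernoulli(1/2) and map to +-1.  Using population rather than sample
    moments keeps the scale identical across batches, so the planted
    coefficients live on the same standardized scale the model fits.
    """
    out = raw.copy()
    for c in out.columns:
        col = out[c].to_numpy()
        if set(np.unique(col)) <= {0.0, 1.0}:
            out[c] = (col - 0.5) / 0.5
    return out


def make_true_beta(m: int, n_nonzero: int, magnitude: float, seed: int) -> np.ndarray:
    """Sparse coefficient vector: ``n_nonzero`` entries of +-magnitude."""
    rng = np.random.default_rng(seed)
    beta = np.zeros(m)
    idx = rng.choice(m, size=n_nonzero, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_nonzero)
    beta[idx] = signs * magnitude
    return beta


def simulate_blocks(config: SimulationConfig):
    """Simulate a matched block design from the model's own process.

    Candidate blocks are drawn until ``n_pairs`` case blocks (>= 1
    associated SNP) and ``n_pairs`` control blocks (none) exist; block
    ``i`` of each label forms matched pair ``i``.  Returns
    ``(blocks, F, truth)`` where ``F`` is the standardized feature
    frame covering every block SNP.
    """
    rng = np.random.default_rng(config.seed)
    beta = make_true_beta(config.m, config.n_nonzero, config.beta_magnitude, config.seed)
    lo, hi = config.block_size_range
    mean_size = 0.5 * (lo + hi)
    p_any = 1.0 - (1.0 - expit(config.alpha)) ** mean_size  # rough case rate
    if p_any < 1e-4:
        raise ValueError(
            "expected case-block rate is vanishingly small; "
            "increase alpha or the planted coefficients"
        )

    case_blocks: list = []
    control_blocks: list = []
    frames: list = []
    assoc: list = []
    snp_counter = 0
    batch_no = 0
    while (len(case_blocks) < config.n_pairs or len(control_blocks) < config.n_pairs):
        if batch_no >= config.max_batches:
            raise RuntimeError(
                f"could not fill {config.n_pairs} case pairs in "
                f"{config.max_batches} batches; the case rate may be too low"
            )
        need_case = config.n_pairs - len(case_blocks)
        n_blocks = max(int(need_case / max(p_any, 0.01) * 1.3), 200)
        sizes = rng.integers(lo, hi + 1, size=n_blocks)
        n_snps = int(sizes.sum())
        raw = simulate_features(
            n_snps, config.m, config.correlation, int(rng.integers(2**31)),
            config.binary_fraction,
        )
        raw.index = [f"snp{snp_counter + i}" for i in range(n_snps)]
        snp_counter += n_snps
        F = _standardize_population(raw)
        eta = config.alpha + F.to_numpy() @ beta
        a = rng.random(n_snps) < expit(eta)
        frames.append(F)
        assoc.append(pd.Series(a.astype(int), index=F.index))
        start = 0
        for size in sizes:
            ids = tuple(F.index[start : start + size])
            has_assoc = bool(a[start : start + size].any())
            start += size
            if has_assoc and len(case_blocks) < config.n_pairs:
                case_blocks.append(ids)
            elif not has_assoc and len(control_blocks) < config.n_pairs:
                control_blocks.append(ids)
        batch_no += 1

    blocks = []
    labels = {}
    for i, (c_ids, t_ids) in enumerate(zip(case_blocks, control_blocks)):
        cb = Block(f"case{i}", "case", c_ids, c_ids[0], pair_id=i)
        tb = Block(f"control{i}", "control", t_ids, t_ids[0], pair_id=i)
        blocks.extend([cb, tb])
        labels[cb.block_id] = "case"
        labels[tb.block_id] = "control"
    F_all = pd.concat(frames)
    assoc_all = pd.concat(assoc)
    kept = [s for b in blocks for s in b.snp_ids]
    truth = TruthBundle(
        alpha=config.alpha,
        beta=beta,
        associated=assoc_all.loc[kept],
        labels=labels,
    )
    return blocks, F_all.loc[kept], truth


def simulate_casecontrol(
    n_cases: int,
    n_controls: int,
    maf: float,
    log_or: float,
    covariate_effects=None,
    seed: int = 0,
    base_rate: float = 0.1,
    max_draws: int = 10_000_000,
) -> SubjectData:
    """Retrospective case-control sample under a logistic disease model.

    Genotypes are Binomial(2, maf) (Hardy-Weinberg); disease risk is
    logistic in the dosage (slope ``log_or``) and any standard-normal
    covariates, with intercept set for a population rate ``base_rate``
    at the genotype mean.  Subjects are simulated and stratified until
    both quotas fill; an unfillable class raises.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("class sizes must be positive")
    effects = np.asarray(covariate_effects if covariate_effects is not None else [], dtype=float)
    rng = np.random.default_rng(seed)
    intercept = float(logit(base_rate)) - log_or * 2.0 * maf
    got_d: list = []
    got_g: list = []
    got_x: list = []
    need = {1: n_cases, 0: n_controls}
    drawn = 0
    while need[1] > 0 or need[0] > 0:
        if drawn >= max_draws:
            raise RuntimeError(
                f"simulated {drawn} subjects without filling both classes "
                f"(still need {need[1]} cases, {need[0]} controls)"
            )
        batch = max(2 * (need[1] + need[0]), 1000)
        drawn += batch
        g = rng.binomial(2, maf, size=batch).astype(float)
        x = rng.standard_normal((batch, len(effects)))
        eta = intercept + log_or * g + (x @ effects if len(effects) else 0.0)
        d = (rng.random(batch) < expit(eta)).astype(int)
        for label in (1, 0):
            take = np.flatnonzero(d == label)[: need[label]]
            need[label] -= len(take)
            got_d.append(d[take])
            got_g.append(g[take])
            got_x.append(x[take])
    D = np.concatenate(got_d)
    G = np.concatenate(got_g)
    X = np.concatenate(got_x)
    order = rng.permutation(len(D))
    return SubjectData(
        D=D[order],
        X=pd.DataFrame(X[order], columns=[f"cov{i + 1}" for i in range(len(effects))]),
        G=pd.DataFrame({"snp": G[order]}),
    )
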