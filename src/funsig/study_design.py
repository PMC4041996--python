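"""Matched case/control SNP-block design.

Case SNPs are known trait-associated variants; each is matched to a
control SNP drawn from a genotyping-platform sampling frame on
chromosome, platform and MAF bin.  Every seed SNP is grouped with its
LD partners (pairwise R^2 >= 0.8) into a block, and matched pairs of
blocks form the training/validation design for the signature model.

All operations are generic table operations on pandas frames; nothing
here queries an external catalog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PLATFORMS",
    "Block",
    "MatchedPairSet",
    "maf_bin",
    "ld_partner_blocks",
    "dedupe_seeds",
    "match_controls",
    "split_pairs",
]

PLATFORMS = ("illumina_only", "affymetrix_only", "both")


@dataclass(frozen=True)
class Block:
    """A seed SNP together with its LD partners, labelled case or control."""

    block_id: str
    label: str
    snp_ids: tuple
    seed_snp: str
    pair_id: int | None = None

    def __post_init__(self) -> None:
        if self.label not in ("case", "control"):
            raise ValueError(f"block label must be 'case' or 'control', got {self.label!r}")
        if len(self.snp_ids) == 0:
            raise ValueError("block must be non-empty")

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class MatchedPairSet:
    """Matched (case block, control block) pairs plus a train/validation split."""

    pairs: list
    unmatched_cases: list = field(default_factory=list)
    split: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def subset(self, which: str) -> list:
        return [p for p in self.pairs if self.split.get(p[0].pair_id) == which]

    @property
    def blocks(self) -> list:
        out = []
        for case, control in self.pairs:
            out.extend([case, control])
        return out


def maf_bin(maf) -> np.ndarray:
    """MAF rounded to the nearest 0.02, as an integer bin index.

    Uses round-half-to-even for values exactly halfway between bins,
    which makes the binning deterministic across platforms.
    """
    return np.asarray(np.round(np.asarray(maf, dtype=float) / 0.02), dtype=int)


def _ld_adjacency(ld_table: pd.DataFrame, threshold: float) -> dict:
    r2 = np.asarray(ld_table["r2"], dtype=float)
    if np.any((r2 < 0) | (r2 > 1)):
        raise ValueError("R^2 values must lie in [0, 1]")
    adj: dict = {}
    keep = r2 >= threshold
    for a, b in zip(ld_table.loc[keep, "snp_a"], ld_table.loc[keep, "snp_b"]):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def ld_partner_blocks(
    seed_snps: Sequence[str],
    ld_table: pd.DataFrame,
    threshold: float = 0.8,
    label: str = "case",
) -> list:
    """One block per seed: the seed plus all SNPs with R^2 >= threshold.

    The comparison is inclusive, so a partner at exactly the threshold
    belongs to the block.  Seeds absent from the LD table yield
    singleton blocks.
    """
    adj = _ld_adjacency(ld_table, threshold)
    blocks = []
    for seed in seed_snps:
        members = (seed,) + tuple(sorted(adj.get(seed, ())))
        blocks.append(Block(block_id=f"{label}:{seed}", label=label, snp_ids=members, seed_snp=seed))
    return blocks


def dedupe_seeds(seeds: Sequence[str], blocks: Sequence[Block], rng_seed: int) -> list:
    """Collapse seeds whose blocks overlap, keeping one random representative.

    Grouping is the transitive closure of pairwise block overlap (seeds
    sharing an LD partner, directly or through a chain, form one group).
    The surviving representative is drawn uniformly per group; the
    partition itself does not depend on input order.
    """
    by_seed = {b.seed_snp: set(b.snp_ids) for b in blocks}
    missing = [s for s in seeds if s not in by_seed]
    if missing:
        raise ValueError(f"no block for seeds: {missing[:5]}")
    g = nx.Graph()
    g.add_nodes_from(seeds)
    membership: dict = {}
    for s in seeds:
        for snp in by_seed[s]:
            membership.setdefault(snp, []).append(s)
    for snp, owners in membership.items():
        for other in owners[1:]:
            g.add_edge(owners[0], other)
    rng = np.random.default_rng(rng_seed)
    keep = set()
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        keep.add(comp[rng.integers(len(comp))])
    return [s for s in seeds if s in keep]


def _check_frame(df: pd.DataFrame, name: str) -> pd.DataFrame:
    required = {"snp_id", "chrom", "maf", "platform"}
    if not required.issubset(df.columns):
        raise ValueError(f"{name} table must have columns {sorted(required)}")
    bad = set(df["platform"]) - set(PLATFORMS)
    if bad:
        raise ValueError(f"unknown platform labels {sorted(bad)}; expected {PLATFORMS}")
    low = df["maf"] < 0.05
    if low.any():
        raise ValueError(
            f"{name} table contains {int(low.sum())} SNPs with MAF < 0.05; "
            "frame membership requires MAF >= 0.05"
        )
    return df


def match_controls(
    cases: pd.DataFrame,
    frame: pd.DataFrame,
    ld_table: pd.DataFrame,
    rng_seed: int,
    threshold: float = 0.8,
) -> MatchedPairSet:
    """Randomly match one control SNP per case on chromosome, platform and MAF bin.

    Frame SNPs in any LD at all (R^2 > 0 in the table) with a case are
    never eligible.  A candidate is also skipped when its LD block would
    share a SNP with any case block or with the block of a control
    chosen earlier.  Matching is sequential, so the case processing
    order matters; it is a seeded random permutation.  Cases with an
    empty eligible set are reported, not fatal.
    """
    cases = _check_frame(cases, "cases").reset_index(drop=True)
    frame = _check_frame(frame, "frame").reset_index(drop=True)
    if set(cases["snp_id"]) & set(frame["snp_id"]):
        raise ValueError("sampling frame must be disjoint from the case SNPs")
    rng = np.random.default_rng(rng_seed)

    case_ids = list(cases["snp_id"])
    case_blocks = {
        b.seed_snp: b for b in ld_partner_blocks(case_ids, ld_table, threshold, label="case")
    }
    case_snp_pool = set().union(*(set(b.snp_ids) for b in case_blocks.values()))

    # frame SNPs with any nonzero R^2 to any case SNP (absent pairs count as 0)
    r2 = np.asarray(ld_table["r2"], dtype=float)
    case_set = set(case_ids)
    in_ld_with_case = set()
    for a, b, r in zip(ld_table["snp_a"], ld_table["snp_b"], r2):
        if r > 0:
            if a in case_set:
                in_ld_with_case.add(b)
            if b in case_set:
                in_ld_with_case.add(a)

    frame_blocks = {
        b.seed_snp: b
        for b in ld_partner_blocks(list(frame["snp_id"]), ld_table, threshold, label="control")
    }

    key = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "platform": frame["platform"],
            "bin": maf_bin(frame["maf"]),
        }
    )
    frame_groups = {k: list(frame.loc[idx, "snp_id"]) for k, idx in key.groupby(
        ["chrom", "platform", "bin"]
    ).groups.items()}

    pairs = []
    unmatched = []
    used_snps = set(case_snp_pool)
    order = rng.permutation(len(cases))
    pair_id = 0
    for i in order:
        row = cases.iloc[int(i)]
        k = (row["chrom"], row["platform"], int(maf_bin(row["maf"])))
        eligible = []
        for cand in frame_groups.get(k, []):
            if cand in in_ld_with_case:
                continue
            if set(frame_blocks[cand].snp_ids) & used_snps:
                continue
            eligible.append(cand)
        if not eligible:
            unmatched.append(row["snp_id"])
            continue
        chosen = eligible[rng.integers(len(eligible))]
        cb = case_blocks[row["snp_id"]]
        ctrl = frame_blocks[chosen]
        case_block = Block(cb.block_id, "case", cb.snp_ids, cb.seed_snp, pair_id=pair_id)
        ctrl_block = Block(ctrl.block_id, "control", ctrl.snp_ids, ctrl.seed_snp, pair_id=pair_id)
        pairs.append((case_block, ctrl_block))
        used_snps |= set(ctrl.snp_ids)
        pair_id += 1
    return MatchedPairSet(pairs=pairs, unmatched_cases=unmatched)


def split_pairs(pair_set: MatchedPairSet, n_train: int, rng_seed: int) -> MatchedPairSet:
    """Label a uniformly random subset of pairs 'train', the rest 'validation'."""
    n = len(pair_set.pairs)
    if n_train > n:
        raise ValueError(f"n_train={n_train} exceeds the number of pairs ({n})")
    if n_train == n:
        warnings.warn("all pairs assigned to training; validation set is empty")
    rng = np.random.default_rng(rng_seed)
    train_ids = set(rng.choice(n, size=n_train, replace=False).tolist())
    split = {}
    for j, (case, _) in enumerate(pair_set.pairs):
        split[case.pair_id] = "train" if j in train_ids else "validation"
    pair_set.split = split
    return pair_set
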