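"""Plain-text readers and writers for the pipeline's tables.

Everything is TSV with a header row; genomic intervals are BED-style
0-based half-open.  The feature matrix travels with a JSON sidecar of
standardization statistics so that signatures fitted on one study can
score another.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_features import BinSummary, FeatureMatrix
from .study_design import Block
from .signature_model import PosteriorDraws

__all__ = [
    "read_bin_summaries",
    "read_bed5",
    "read_snp_table",
    "read_ld_table",
    "write_blocks",
    "read_blocks",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_draws",
    "read_draws",
    "read_dosage_tsv",
    "read_vcf_dosage",
]


def read_bin_summaries(path) -> list:
    df = pd.read_csv(path, sep="\t")
    required = {"bin_id", "chrom", "start", "end", "n", "min", "range", "sum", "sumsq"}
    if not required.issubset(df.columns):
        raise ValueError(f"bin summary table needs columns {sorted(required)}")
    return [
        BinSummary(
            bin_id=str(r.bin_id), chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            n=int(r.n), min=float(r.min), range=float(r.range),
            sum=float(r.sum), sumsq=float(r.sumsq),
        )
        for r in df.itertuples()
    ]


def read_bed5(path) -> pd.DataFrame:
    """BED5 interval track (chrom, start, end, name, score), no header."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score"],
        dtype={"chrom": str},
    )
    return df


def read_snp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "snp_id" not in df.columns:
        raise ValueError("SNP table needs an 'snp_id' column")
    return df.set_index("snp_id")


def read_ld_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"snp_a", "snp_b", "r2"}.issubset(df.columns):
        raise ValueError("LD table needs columns snp_a, snp_b, r2")
    return df


def write_blocks(blocks, path, split: dict | None = None) -> None:
    rows = []
    for b in blocks:
        for s in b.snp_ids:
            rows.append(
                {
                    "block_id": b.block_id,
                    "label": b.label,
                    "pair_id": b.pair_id if b.pair_id is not None else -1,
                    "snp_id": s,
                    "is_seed": int(s == b.seed_snp),
                    "split": (split or {}).get(b.pair_id, ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_blocks(path):
    df = pd.read_csv(path, sep="\t")
    blocks = []
    split = {}
    for (bid, label, pid), grp in df.groupby(["block_id", "label", "pair_id"], sort=False):
        seeds = grp.loc[grp["is_seed"] == 1, "snp_id"]
        seed = str(seeds.iloc[0]) if len(seeds) else str(grp["snp_id"].iloc[0])
        pair_id = None if pid == -1 else int(pid)
        blocks.append(
            Block(str(bid), str(label), tuple(grp["snp_id"].astype(str)), seed, pair_id=pair_id)
        )
        if "split" in grp.columns and isinstance(grp["split"].iloc[0], str) and grp["split"].iloc[0]:
            split[pair_id] = grp["split"].iloc[0]
    return blocks, split


def write_feature_matrix(fm: FeatureMatrix, path, stats_path) -> None:
    fm.frame.rename_axis("snp_id").to_csv(path, sep="\t")
    stats = {
        "columns": list(fm.frame.columns),
        "means": {c: float(v) for c, v in fm.means.items()},
        "sds": {c: float(v) for c, v in fm.sds.items()},
        "dropped": list(fm.dropped),
        "pca_loadings": {
            cls: np.asarray(l).tolist() for cls, l in fm.pca_loadings.items()
        },
    }
    Path(stats_path).write_text(json.dumps(stats, indent=1))


def read_feature_matrix(path, stats_path) -> FeatureMatrix:
    frame = pd.read_csv(path, sep="\t").set_index("snp_id")
    stats = json.loads(Path(stats_path).read_text())
    return FeatureMatrix(
        frame=frame[stats["columns"]],
        means=pd.Series(stats["means"]),
        sds=pd.Series(stats["sds"]),
        dropped=list(stats["dropped"]),
        pca_loadings={
            cls: np.asarray(l) for cls, l in stats.get("pca_loadings", {}).items()
        },
    )


def read_feature_stats(stats_path) -> FeatureMatrix:
    """Standardization statistics alone (for scoring new SNPs)."""
    stats = json.loads(Path(stats_path).read_text())
    return FeatureMatrix(
        frame=pd.DataFrame(columns=stats["columns"], dtype=float),
        means=pd.Series(stats["means"]),
        sds=pd.Series(stats["sds"]),
        dropped=list(stats["dropped"]),
        pca_loadings={
            cls: np.asarray(l) for cls, l in stats.get("pca_loadings", {}).items()
        },
    )


def write_draws(draws: PosteriorDraws, path) -> None:
    draws.to_frame().to_csv(path, sep="\t", index=False)


def read_draws(path) -> PosteriorDraws:
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c not in ("chain", "alpha")]
    return PosteriorDraws(
        alpha=df["alpha"].to_numpy(),
        beta=df[cols].to_numpy(),
        chain=df["chain"].to_numpy(dtype=int),
        columns=tuple(cols),
    )


def read_dosage_tsv(path) -> pd.DataFrame:
    """Subjects-by-SNPs dosage matrix; first column is the subject id."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0]).astype(float)


def read_vcf_dosage(path) -> pd.DataFrame:
    """Dosages from a minimal uncompressed VCF: GT alleles summed per subject.

    Missing alleles ('.') make the dosage NaN for that subject/SNP.
    """
    samples: list = []
    ids: list = []
    rows: list = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            fmt = fields[8].split(":")
            try:
                gt_i = fmt.index("GT")
            except ValueError as err:
                raise ValueError("VCF records need a GT field") from err
            ids.append(fields[2] if fields[2] != "." else f"{fields[0]}:{fields[1]}")
            dose = []
            for sample in fields[9:]:
                gt = sample.split(":")[gt_i].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    dose.append(np.nan)
                else:
                    dose.append(float(sum(int(a) > 0 for a in alleles)))
            rows.append(dose)
    if not samples:
        raise ValueError("no #CHROM header line found; not a VCF?")
    return pd.DataFrame(np.asarray(rows).T, index=samples, columns=ids)
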