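"""Build the standardized per-SNP annotation matrix F.

Raw annotation sources come in four shapes:

* binned signal summaries (ChIP-seq / RNA-seq style): per-bin count,
  minimum, range, sum and sum-of-squares, from which mean, z
  (mean / sd) and maximum are derived and log-transformed;
* conservation range summaries (PhyloP style): per-range mean / sd
  assigned to the SNPs inside the range;
* scored interval tracks (BED5): transcription-factor or DNase
  clusters, summarised per SNP as overlap counts / indicators and
  log-scores, coded 0 outside any cluster;
* categorical labels: dbSNP-style function classes and RegulomeDB
  categories, expanded to reference-coded indicator blocks.

High-dimensional signal classes are reduced by PCA on standardized
columns, keeping the smallest number of components that explains a
target fraction (90% by default) of the variance.  The assembled
matrix is standardized column-wise; scoring new SNPs always reuses the
stored training means and SDs so that fitted signatures transport to
new studies.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.decomposition import PCA

__all__ = [
    "TABLE_ROSTER",
    "FUNCTION_CLASSES",
    "BinSummary",
    "FeatureMatrix",
    "NaturalSplineBasis",
    "derive_bin_features",
    "standardize_phylop",
    "interval_features",
    "encode_function_class",
    "encode_regulomedb",
    "pca_reduce",
    "maf_spline_basis",
    "assemble_feature_matrix",
]

#: Column roster of the 57-predictor annotation model, in canonical order.
TABLE_ROSTER = (
    ["MAF1", "MAF2", "MAF3", "MAF4"]
    + ["funcIntron", "funcNg3", "funcNg5", "funcNonsynon", "funcSynon", "funcUTR"]
    + [f"PhyPC{i}" for i in range(1, 5)]
    + ["IndelInd", "CNVInd", "InvInd"]
    + [f"BrPC{i}" for i in range(1, 19)]
    + [f"CalPC{i}" for i in range(1, 12)]
    + ["logDNase", "TFBSfreq", "logTFBS", "ORegInd", "PPh2Prob"]
    + [f"rDBcat{i}" for i in range(1, 7)]
)

#: dbSNP-style primary function classes and the indicator each one sets.
#: 'missense' and 'nonsense' merge into coding-nonsynonymous; the two
#: untranslated classes merge into one UTR indicator; 'unknown' is the
#: reference class (all indicators zero).
FUNCTION_CLASSES = {
    "unknown": None,
    "intron": "funcIntron",
    "near-gene-3": "funcNg3",
    "near-gene-5": "funcNg5",
    "missense": "funcNonsynon",
    "nonsense": "funcNonsynon",
    "coding-synon": "funcSynon",
    "untranslated-3": "funcUTR",
    "untranslated-5": "funcUTR",
}

_FUNC_COLUMNS = ["funcIntron", "funcNg3", "funcNg5", "funcNonsynon", "funcSynon", "funcUTR"]
_RDB_COLUMNS = [f"rDBcat{i}" for i in range(1, 7)]


class DegenerateBinError(ValueError):
    """Raised for bins whose summaries cannot support a variance."""


class InconsistentSummaryError(ValueError):
    """Raised when (n, sum, sumsq) cannot come from a real-valued sample."""


@dataclass(frozen=True)
class BinSummary:
    """Summary statistics of a signal track within one genomic bin.

    ``n`` valid data points with the given minimum, range, sum and
    sum-of-squares; the interval [start, end) locates the bin.
    """

    bin_id: str
    n: int
    min: float
    range: float
    sum: float
    sumsq: float
    chrom: str = ""
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"bin {self.bin_id}: n must be nonnegative")
        if self.range < 0:
            raise ValueError(f"bin {self.bin_id}: range must be nonnegative")
        if self.sumsq < 0:
            raise ValueError(f"bin {self.bin_id}: sum of squares must be nonnegative")


def _bin_moments(b: BinSummary) -> tuple:
    """(mean_with_zero_sum_rule, sd) from a bin summary, n-1 denominator."""
    ss_about_mean = b.sumsq - b.sum**2 / b.n
    if ss_about_mean < -1e-9 * max(b.sumsq, 1.0):
        raise InconsistentSummaryError(
            f"bin {b.bin_id}: sumsq {b.sumsq} < sum^2/n {b.sum ** 2 / b.n}"
        )
    effective_sum = 1.0 if b.sum == 0 else b.sum
    mean = effective_sum / b.n
    sd = math.sqrt(max(ss_about_mean, 0.0) / (b.n - 1))
    return mean, sd


def _safe_log(x: float) -> float:
    """Natural log with the absent-signal convention: non-positive -> 0."""
    return math.log(x) if x > 0 else 0.0


def derive_bin_features(b: BinSummary) -> dict:
    """Log signal strength, consistency and peak height for one bin.

    Derives mean = sum/n (a zero sum is set to one first), z = mean/sd
    with the sample (n-1) standard deviation, and max = min + range,
    all on the natural-log scale.  A zero sd, or a non-positive mean or
    maximum, falls back to a log-feature of 0, the same convention used
    for SNPs outside any scored cluster.
    """
    if b.n < 2:
        raise DegenerateBinError(f"bin {b.bin_id}: need n >= 2, got {b.n}")
    mean, sd = _bin_moments(b)
    z = mean / sd if sd > 0 else 0.0
    peak = b.min + b.range
    return {
        "log_mean": _safe_log(mean),
        "log_z": _safe_log(z) if sd > 0 else 0.0,
        "log_max": _safe_log(peak),
    }


def standardize_phylop(ranges, snps: pd.DataFrame) -> pd.DataFrame:
    """Assign each SNP the standardized conservation score of its range.

    Each range contributes mean / sd of its raw summaries (no zero-sum
    substitution here: conservation scores are signed).  Ranges must
    not overlap within a track; ranges with n < 2 are skipped with a
    warning.  SNPs covered by no range get score 0 and a missing flag —
    after standardization 0 is the training mean, a neutral imputation.
    """
    required = {"chrom", "pos"}
    if not required.issubset(snps.columns):
        raise ValueError("snps frame needs 'chrom' and 'pos' columns")
    trees: dict = {}
    for r in ranges:
        if r.n < 2:
            warnings.warn(f"range {r.bin_id} has n={r.n} < 2; skipped")
            continue
        mean = r.sum / r.n
        ss = r.sumsq - r.sum**2 / r.n
        if ss < -1e-9 * max(r.sumsq, 1.0):
            raise InconsistentSummaryError(f"range {r.bin_id}: inconsistent sumsq")
        sd = math.sqrt(max(ss, 0.0) / (r.n - 1))
        score = mean / sd if sd > 0 else 0.0
        tree = trees.setdefault(str(r.chrom), IntervalTree())
        if tree.overlap(r.start, r.end):
            raise ValueError(f"range {r.bin_id} overlaps another range on {r.chrom}")
        tree.addi(r.start, r.end, score)
    scores = np.zeros(len(snps))
    missing = np.ones(len(snps), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(snps["chrom"], snps["pos"])):
        tree = trees.get(str(chrom))
        if tree is None:
            continue
        hits = tree.at(int(pos))
        if hits:
            scores[i] = next(iter(hits)).data
            missing[i] = False
    return pd.DataFrame({"score": scores, "missing": missing}, index=snps.index)


def interval_features(
    snps: pd.DataFrame, track: pd.DataFrame, mode: str = "count_meanlogscore"
) -> pd.DataFrame:
    """Summarise a scored interval track at each SNP position.

    ``count_meanlogscore`` returns the number of clusters the SNP
    intersects and the mean natural-log score over them;
    ``indicator_logscore`` returns a 0/1 overlap indicator and the
    log score of the containing cluster (averaged if clusters overlap).
    Either way a SNP outside every cluster is coded (0, 0).
    """
    if mode not in ("count_meanlogscore", "indicator_logscore"):
        raise ValueError(f"unknown mode {mode!r}")
    required = {"chrom", "start", "end", "score"}
    if not required.issubset(track.columns):
        raise ValueError("track needs chrom/start/end/score columns")
    if (np.asarray(track["score"], dtype=float) <= 0).any():
        raise ValueError("scored tracks must have positive scores")
    if (np.asarray(track["start"]) >= np.asarray(track["end"])).any():
        raise ValueError("intervals must satisfy start < end")
    trees: dict = {}
    for chrom, start, end, score in zip(
        track["chrom"], track["start"], track["end"], track["score"]
    ):
        trees.setdefault(str(chrom), IntervalTree()).addi(int(start), int(end), float(score))
    first = np.zeros(len(snps))
    second = np.zeros(len(snps))
    for i, (chrom, pos) in enumerate(zip(snps["chrom"], snps["pos"])):
        tree = trees.get(str(chrom))
        hits = tree.at(int(pos)) if tree is not None else ()
        if not hits:
            continue
        logs = [math.log(h.data) for h in hits]
        if mode == "count_meanlogscore":
            first[i] = len(hits)
        else:
            first[i] = 1.0
        second[i] = float(np.mean(logs))
    names = (
        ("count", "mean_log_score")
        if mode == "count_meanlogscore"
        else ("indicator", "log_score")
    )
    return pd.DataFrame({names[0]: first, names[1]: second}, index=snps.index)


def encode_function_class(primary_class: str) -> pd.Series:
    """Expand a dbSNP-style primary function class to six 0/1 indicators."""
    label = str(primary_class).replace("–", "-").replace("—", "-").strip().lower()
    if label not in FUNCTION_CLASSES:
        raise ValueError(
            f"unrecognised function class {primary_class!r}; "
            f"accepted: {sorted(FUNCTION_CLASSES)}"
        )
    out = pd.Series(0, index=_FUNC_COLUMNS, dtype=int)
    col = FUNCTION_CLASSES[label]
    if col is not None:
        out[col] = 1
    return out


def encode_regulomedb(category: int) -> pd.Series:
    """Expand a RegulomeDB category (1..7) to six indicators; 7 is baseline."""
    category = int(category)
    if not 1 <= category <= 7:
        raise ValueError(f"RegulomeDB category must be in 1..7, got {category}")
    out = pd.Series(0, index=_RDB_COLUMNS, dtype=int)
    if category <= 6:
        out[f"rDBcat{category}"] = 1
    return out


def pca_reduce(X, variance_fraction: float = 0.90):
    """Correlation PCA keeping enough components for the variance target.

    Columns are standardized (constant columns dropped with a warning)
    before the decomposition, so this is PCA of the correlation matrix.
    Returns (loadings, scores, k) where k is the smallest number of
    components whose cumulative explained-variance fraction reaches
    ``variance_fraction``; ``loadings`` has one orthonormal row per
    retained component, signed so its largest-magnitude entry is
    positive, and ``scores = X_std @ loadings.T``.
    """
    X = pd.DataFrame(X).copy()
    if X.shape[1] < 2:
        if X.shape[1] == 0:
            raise ValueError("need at least one column")
    if X.isna().to_numpy().any():
        raise ValueError("PCA input must not contain missing values")
    sds = X.std(ddof=1)
    constant = sds.index[sds == 0.0].tolist()
    if constant:
        warnings.warn(f"dropping constant columns before PCA: {constant}")
        X = X.drop(columns=constant)
        sds = sds.drop(constant)
    Z = (X - X.mean()) / sds
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    evr = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(evr), variance_fraction - 1e-12) + 1)
    loadings = pca.components_[:k]
    flip = np.sign(loadings[np.arange(k), np.argmax(np.abs(loadings), axis=1)])
    loadings = loadings * flip[:, None]
    scores = scores[:, :k] * flip[None, :]
    return loadings, scores, k


class NaturalSplineBasis:
    """Natural cubic spline basis for MAF, linear beyond the boundary knots.

    Built from the truncated-power representation: with knots
    ``k_1 < ... < k_K`` the basis is ``x, N_1, ..., N_{K-2}`` where
    ``N_j(x) = d_j(x) - d_{K-1}(x)`` and
    ``d_j(x) = ((x - k_j)_+^3 - (x - k_K)_+^3) / (k_K - k_j)``.
    Boundary knots sit at MAF 0.05 and 0.5; with three interior knots at
    the training-MAF quartiles this yields exactly four columns.
    """

    def __init__(self, knots):
        knots = np.asarray(sorted(knots), dtype=float)
        if len(np.unique(knots)) != len(knots):
            raise ValueError("spline knots must be distinct")
        if len(knots) < 3:
            raise ValueError("need at least three knots")
        self.knots = knots

    @classmethod
    def from_training(cls, maf, boundary=(0.05, 0.5)) -> "NaturalSplineBasis":
        maf = np.asarray(maf, dtype=float)
        interior = np.quantile(maf, [0.25, 0.5, 0.75])
        lo, hi = boundary
        interior = interior[(interior > lo) & (interior < hi)]
        return cls(np.concatenate([[lo], np.unique(interior), [hi]]))

    def __call__(self, maf) -> np.ndarray:
        x = np.atleast_1d(np.asarray(maf, dtype=float))
        if np.any((x < 0.0) | (x > 0.5)):
            raise ValueError("MAF must lie in [0, 0.5]")
        k = self.knots
        K = len(k)

        def d(j):
            return (
                np.clip(x - k[j], 0.0, None) ** 3 - np.clip(x - k[-1], 0.0, None) ** 3
            ) / (k[-1] - k[j])

        dlast = d(K - 2)
        cols = [x] + [d(j) - dlast for j in range(K - 2)]
        return np.column_stack(cols)


def maf_spline_basis(maf, basis: NaturalSplineBasis | None = None, training_maf=None):
    """Four-column natural-spline expansion of MAF (columns MAF1..MAF4).

    Provide either a fitted ``NaturalSplineBasis`` or the training MAFs
    used to place the interior knots.
    """
    if basis is None:
        if training_maf is None:
            training_maf = maf
        basis = NaturalSplineBasis.from_training(training_maf)
    values = basis(maf)
    cols = [f"MAF{i}" for i in range(1, values.shape[1] + 1)]
    idx = maf.index if isinstance(maf, pd.Series) else None
    return pd.DataFrame(values, columns=cols, index=idx), basis


@dataclass
class FeatureMatrix:
    """Standardized annotation matrix plus the statistics that built it.

    ``pca_loadings`` optionally stores, per reduced annotation class,
    the retained component loadings so that scoring can project new
    SNPs onto the training components.
    """

    frame: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    dropped: list = field(default_factory=list)
    pca_loadings: dict = field(default_factory=dict)

    @property
    def snp_ids(self):
        return list(self.frame.index)

    @property
    def columns(self):
        return list(self.frame.columns)

    def __getitem__(self, cols):
        return self.frame[cols]


def assemble_feature_matrix(
    features: pd.DataFrame | dict,
    stats: FeatureMatrix | None = None,
) -> FeatureMatrix:
    """Concatenate per-class feature blocks and standardize.

    With ``stats=None`` (training) the column means and SDs are
    computed from these rows; constant columns are dropped with a
    warning.  Otherwise the stored training statistics are applied
    unchanged (scoring), and a stored column absent from the input —
    or an input SNP with a missing value — is an error.

    Columns named in the canonical roster are emitted in roster order,
    ahead of any extra columns.
    """
    if isinstance(features, dict):
        parts = list(features.values())
        idx = parts[0].index
        for part in parts[1:]:
            if not part.index.equals(idx):
                missing = idx.difference(part.index).tolist() + part.index.difference(idx).tolist()
                raise ValueError(f"feature blocks disagree on SNPs: {missing[:5]}")
        raw = pd.concat(parts, axis=1)
    else:
        raw = features.copy()
    if raw.columns.duplicated().any():
        dupes = raw.columns[raw.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature columns: {dupes}")
    na_mask = raw.isna()
    if na_mask.to_numpy().any():
        snp = raw.index[na_mask.any(axis=1)][0]
        col = raw.columns[na_mask.loc[snp]][0]
        raise ValueError(f"SNP {snp!r} is missing feature {col!r}")
    in_roster = [c for c in TABLE_ROSTER if c in raw.columns]
    extra = [c for c in raw.columns if c not in TABLE_ROSTER]
    raw = raw[in_roster + extra].astype(float)

    if stats is None:
        means = raw.mean()
        sds = raw.std(ddof=1)
        constant = sds.index[sds == 0.0].tolist()
        if constant:
            warnings.warn(f"dropping constant feature columns: {constant}")
            raw = raw.drop(columns=constant)
            means = means.drop(constant)
            sds = sds.drop(constant)
        frame = (raw - means) / sds
        return FeatureMatrix(frame=frame, means=means, sds=sds, dropped=constant)

    unknown = [c for c in stats.means.index if c not in raw.columns]
    if unknown:
        raise ValueError(f"stored statistics refer to absent columns: {unknown}")
    raw = raw[list(stats.means.index)]
    frame = (raw - stats.means) / stats.sds
    return FeatureMatrix(frame=frame, means=stats.means, sds=stats.sds, dropped=list(stats.dropped))
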