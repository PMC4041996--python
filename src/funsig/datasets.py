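"""Small bundled reference tables.

The ovarian-cancer evaluation table lists the eleven published,
confirmed susceptibility variants for epithelial ovarian cancer
("true positives") as ranked by a ~2.5M-SNP GWAS analysis with
(``rank_af``) and without (``rank_a``) functional signatures.
``lo_f`` is each variant's prior log-odds of association given its
functional annotations and ``log_bf`` the natural-log Bayes factor
from the genotype data.  These published per-variant values are inputs
for the follow-up summaries, not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["ovarian_true_positives", "TRAINING_SNP_COUNTS"]

#: Expected-count inputs behind the intercept prior: at least 1,675 of
#: the 48,888 training-set SNPs are expected to be trait associated.
TRAINING_SNP_COUNTS = {"n_expected_associated": 1675, "n_training_snps": 48888}

_TRUE_POSITIVES = [
    # snp_id, locus, maf, lo_f, log_bf, rank_a, rank_af
    ("rs2072590", "2q31", 0.34, 1.46, 8.63, 65, 59),
    ("rs2665390", "3q25", 0.09, 0.77, 8.08, 77, 73),
    ("rs10069690", "5p15", 0.23, 0.91, -1.38, 1_549_122, 651_710),
    ("rs11782652", "8q21", 0.08, 0.22, 2.98, 5_272, 6_843),
    ("rs7814937", "8q24", 0.12, 1.54, 14.61, 21, 16),
    ("rs3814113", "9p22", 0.30, -0.09, 14.01, 38, 38),
    ("rs7084454", "10p12", 0.31, 1.44, 1.19, 45_616, 12_221),
    ("rs757210", "17q12", 0.37, 1.74, 2.31, 11_630, 2_411),
    ("rs2077606", "17q21", 0.18, 0.70, -0.25, 339_456, 200_494),
    ("rs9303542", "17q21", 0.27, 0.05, 3.70, 2_276, 3_532),
    ("rs8170", "19p13", 0.19, 0.82, 2.72, 7_133, 4_179),
]


def ovarian_true_positives() -> pd.DataFrame:
    """The eleven confirmed ovarian-cancer variants with published ranks."""
    df = pd.DataFrame(
        _TRUE_POSITIVES,
        columns=["snp_id", "locus", "maf", "lo_f", "log_bf", "rank_a", "rank_af"],
    )
    return df.set_index("snp_id")
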