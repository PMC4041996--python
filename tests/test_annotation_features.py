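"""Annotation feature construction: bin summaries, tracks, encodings, PCA, splines."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from funsig.annotation_features import (
    BinSummary,
    DegenerateBinError,
    InconsistentSummaryError,
    NaturalSplineBasis,
    TABLE_ROSTER,
    assemble_feature_matrix,
    derive_bin_features,
    encode_function_class,
    encode_regulomedb,
    interval_features,
    maf_spline_basis,
    pca_reduce,
    standardize_phylop,
)


def _bin(n, s, ss, mn=0.0, rg=0.0, **kw):
    return BinSummary(bin_id="b", n=n, min=mn, range=rg, sum=s, sumsq=ss, **kw)


class TestBinFeatures:
    def test_zero_sum_set_to_one(self):
        feats = derive_bin_features(_bin(10, 0.0, 0.0))
        assert feats["log_mean"] == pytest.approx(math.log(0.1), abs=1e-12)

    def test_matches_direct_computation(self):
        # summaries of the raw signal vector (0, 2, 2, 4)
        feats = derive_bin_features(_bin(4, 8.0, 24.0, mn=1.0, rg=5.0))
        assert feats["log_mean"] == pytest.approx(math.log(2.0), abs=1e-10)
        assert feats["log_z"] == pytest.approx(math.log(2.0 / math.sqrt(8.0 / 3.0)), abs=1e-10)
        assert feats["log_max"] == pytest.approx(math.log(6.0), abs=1e-10)

    def test_constant_signal_fallbacks(self):
        feats = derive_bin_features(_bin(3, 3.0, 3.0, mn=1.0, rg=0.0))
        assert feats["log_z"] == 0.0
        assert feats["log_max"] == 0.0

    def test_degenerate_and_inconsistent_bins(self):
        with pytest.raises(DegenerateBinError):
            derive_bin_features(_bin(1, 1.0, 1.0))
        with pytest.raises(InconsistentSummaryError):
            derive_bin_features(_bin(4, 8.0, 10.0))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=50.0),
            min_size=2,
            max_size=30,
        )
    )
    def test_agrees_with_raw_vector(self, values):
        """Summaries of any raw vector reproduce its mean, z and max."""
        x = np.asarray(values)
        b = _bin(
            len(x), float(x.sum()), float((x**2).sum()),
            mn=float(x.min()), rg=float(np.ptp(x)),
        )
        feats = derive_bin_features(b)
        mean = x.mean() if x.sum() != 0 else 1.0 / len(x)
        sd = x.std(ddof=1)
        assert feats["log_mean"] == pytest.approx(math.log(mean), abs=1e-8)
        if sd > 1e-8 and mean / sd > 1e-12:
            assert feats["log_z"] == pytest.approx(math.log(mean / sd), abs=1e-6)
        assert feats["log_max"] == pytest.approx(math.log(x.max()), abs=1e-8)


class TestPhylopStandardization:
    def test_zero_mean_range_scores_zero(self):
        # raw data (-1, 1): sum 0, sumsq 2
        ranges = [BinSummary("r1", n=2, min=-1, range=2, sum=0.0, sumsq=2.0, chrom="1", start=0, end=100)]
        snps = pd.DataFrame({"chrom": ["1"], "pos": [50]}, index=["s1"])
        out = standardize_phylop(ranges, snps)
        assert out.loc["s1", "score"] == 0.0
        assert not out.loc["s1", "missing"]

    def test_score_is_mean_over_sd(self):
        ranges = [BinSummary("r1", n=4, min=0, range=4, sum=8.0, sumsq=24.0, chrom="1", start=0, end=100)]
        snps = pd.DataFrame({"chrom": ["1", "1"], "pos": [10, 99]}, index=["a", "b"])
        out = standardize_phylop(ranges, snps)
        expected = 2.0 / math.sqrt(8.0 / 3.0)
        assert np.allclose(out["score"], expected, atol=1e-10)

    def test_uncovered_snp_flagged_missing(self):
        ranges = [BinSummary("r1", n=4, min=0, range=4, sum=8.0, sumsq=24.0, chrom="1", start=0, end=100)]
        snps = pd.DataFrame({"chrom": ["2"], "pos": [50]}, index=["s"])
        out = standardize_phylop(ranges, snps)
        assert out.loc["s", "score"] == 0.0
        assert bool(out.loc["s", "missing"])

    def test_small_range_skipped_with_warning(self):
        ranges = [BinSummary("r1", n=1, min=0, range=0, sum=1.0, sumsq=1.0, chrom="1", start=0, end=10)]
        snps = pd.DataFrame({"chrom": ["1"], "pos": [5]}, index=["s"])
        with pytest.warns(UserWarning, match="skipped"):
            out = standardize_phylop(ranges, snps)
        assert bool(out.loc["s", "missing"])


class TestIntervalFeatures:
    @staticmethod
    def _snps(positions, chrom="1"):
        return pd.DataFrame(
            {"chrom": [chrom] * len(positions), "pos": positions},
            index=[f"s{i}" for i in range(len(positions))],
        )

    def test_no_overlap_codes_zero(self):
        track = pd.DataFrame({"chrom": ["1"], "start": [100], "end": [200], "score": [500.0]})
        out = interval_features(self._snps([10]), track)
        assert out.iloc[0].tolist() == [0.0, 0.0]

    def test_count_and_mean_log_score(self):
        track = pd.DataFrame(
            {"chrom": ["1", "1"], "start": [0, 40], "end": [100, 60], "score": [100.0, 1000.0]}
        )
        out = interval_features(self._snps([50]), track, mode="count_meanlogscore")
        assert out.iloc[0, 0] == 2
        assert out.iloc[0, 1] == pytest.approx((math.log(100) + math.log(1000)) / 2, abs=1e-10)

    def test_indicator_mode_half_open(self):
        track = pd.DataFrame({"chrom": ["1"], "start": [70], "end": [71], "score": [1000.0]})
        out = interval_features(self._snps([70, 71]), track, mode="indicator_logscore")
        assert out.iloc[0].tolist() == pytest.approx([1.0, math.log(1000.0)], abs=1e-10)
        assert out.iloc[1].tolist() == [0.0, 0.0]  # end is exclusive

    def test_order_and_split_invariance(self, rng):
        snps = self._snps(list(range(0, 200, 7)))
        track = pd.DataFrame(
            {"chrom": "1", "start": [0, 50, 120], "end": [80, 150, 180], "score": [10.0, 20.0, 30.0]}
        )
        shuffled = track.sample(frac=1, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            interval_features(snps, track), interval_features(snps, shuffled)
        )
        # splitting an interval: counts see both pieces, indicator mode is
        # unchanged for SNPs interior to one piece
        split = pd.DataFrame(
            {"chrom": "1", "start": [0, 30, 50, 120], "end": [30, 80, 150, 180],
             "score": [10.0, 10.0, 20.0, 30.0]}
        )
        a = interval_features(snps, track, mode="indicator_logscore")
        b = interval_features(snps, split, mode="indicator_logscore")
        interior = [p not in (30,) for p in snps["pos"]]
        pd.testing.assert_frame_equal(a.loc[interior], b.loc[interior])

    def test_nonpositive_score_rejected(self):
        track = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [10], "score": [0.0]})
        with pytest.raises(ValueError, match="positive"):
            interval_features(self._snps([5]), track)


class TestEncodings:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("nonsense", "funcNonsynon"),
            ("missense", "funcNonsynon"),
            ("untranslated-5", "funcUTR"),
            ("untranslated-3", "funcUTR"),
            ("intron", "funcIntron"),
            ("near-gene-3", "funcNg3"),
            ("near-gene-5", "funcNg5"),
            ("coding-synon", "funcSynon"),
        ],
    )
    def test_function_class_merging(self, label, expected):
        out = encode_function_class(label)
        assert out[expected] == 1
        assert out.sum() == 1

    def test_unknown_is_reference(self):
        assert encode_function_class("unknown").sum() == 0

    def test_unrecognised_label_errors(self):
        with pytest.raises(ValueError, match="accepted"):
            encode_function_class("promoter")

    @pytest.mark.parametrize("cat", range(1, 8))
    def test_regulomedb_categories(self, cat):
        out = encode_regulomedb(cat)
        if cat == 7:
            assert out.sum() == 0
        else:
            assert out[f"rDBcat{cat}"] == 1 and out.sum() == 1

    @pytest.mark.parametrize("cat", [0, 8, -1])
    def test_regulomedb_out_of_range(self, cat):
        with pytest.raises(ValueError):
            encode_regulomedb(cat)


class TestPCA:
    def test_rank_one_input(self, rng):
        x = rng.standard_normal(100)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        loadings, scores, k = pca_reduce(X, 0.90)
        assert k == 1

    def test_single_column(self, rng):
        x = rng.standard_normal(50)
        _, scores, k = pca_reduce(pd.DataFrame({"a": x}), 0.90)
        z = (x - x.mean()) / x.std(ddof=1)
        assert k == 1
        assert np.allclose(np.abs(scores[:, 0]), np.abs(z), atol=1e-8)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 5)), columns=list("abcde"))
        loadings, scores, k = pca_reduce(X, 0.90)
        Z = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        evals, evecs = np.linalg.eigh(np.cov(Z, rowvar=False))
        evals, evecs = evals[::-1], evecs[:, ::-1]
        frac = evals / evals.sum()
        assert np.cumsum(frac)[k - 1] >= 0.90 > (np.cumsum(frac)[k - 2] if k > 1 else 0.0)
        for i in range(k):
            dot = abs(loadings[i] @ evecs[:, i])
            assert dot == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-10)
        # sign convention: largest-magnitude loading positive
        for row in loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_constant_column_dropped(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(30), "b": np.ones(30)})
        with pytest.warns(UserWarning, match="constant"):
            _, _, k = pca_reduce(X, 0.90)
        assert k == 1


class TestMafSpline:
    def test_four_columns_and_determinism(self, rng):
        maf = rng.uniform(0.05, 0.5, 300)
        B1, basis = maf_spline_basis(maf)
        B2, _ = maf_spline_basis(maf, basis=basis)
        assert list(B1.columns) == ["MAF1", "MAF2", "MAF3", "MAF4"]
        pd.testing.assert_frame_equal(B1, B2)

    def test_constant_maf_centers_to_zero(self):
        basis = NaturalSplineBasis([0.05, 0.2, 0.3, 0.4, 0.5])
        B, _ = maf_spline_basis(np.full(20, 0.3), basis=basis)
        centered = B - B.mean()
        assert np.allclose(centered.to_numpy(), 0.0, atol=1e-14)

    def test_out_of_range_maf(self):
        basis = NaturalSplineBasis([0.05, 0.2, 0.3, 0.4, 0.5])
        with pytest.raises(ValueError, match="MAF"):
            basis(np.array([0.6]))

    def test_spans_natural_cubic_splines(self):
        """Independent construction: cubic B-splines constrained to zero
        second derivative beyond the boundary knots span the same space."""
        from scipy.interpolate import BSpline

        knots = np.array([0.05, 0.15, 0.25, 0.35, 0.5])
        basis = NaturalSplineBasis(knots)
        x = np.linspace(0.05, 0.5, 401)  # the knot span; linear tails tested separately
        B = basis(x)

        t = np.concatenate([[knots[0]] * 4, knots[1:-1], [knots[-1]] * 4])
        n_b = len(t) - 4
        cubic = np.column_stack(
            [BSpline(t, np.eye(n_b)[i], 3, extrapolate=True)(x) for i in range(n_b)]
        )
        # natural constraints: f'' = 0 at both boundary knots
        d2 = np.column_stack(
            [BSpline(t, np.eye(n_b)[i], 3).derivative(2)(np.array(knots[[0, -1]])) for i in range(n_b)]
        )
        null = np.linalg.svd(d2)[2][2:].T  # basis of the constraint null space
        natural = cubic @ null
        design = np.column_stack([np.ones_like(x), natural])
        for j in range(B.shape[1]):
            resid = B[:, j] - design @ np.linalg.lstsq(design, B[:, j], rcond=None)[0]
            assert np.max(np.abs(resid)) < 1e-10

    def test_linear_beyond_boundary_knots(self):
        basis = NaturalSplineBasis([0.05, 0.2, 0.3, 0.4, 0.45])
        x = np.linspace(0.455, 0.5, 50)
        B = basis(x)
        for j in range(B.shape[1]):
            # second differences of a linear function vanish
            assert np.max(np.abs(np.diff(B[:, j], 2))) < 1e-10


class TestAssemble:
    @staticmethod
    def _raw(rng, n=40):
        idx = [f"s{i}" for i in range(n)]
        return pd.DataFrame(
            rng.standard_normal((n, 3)), index=idx, columns=["PPh2Prob", "logDNase", "extra_col"]
        )

    def test_training_standardization(self, rng):
        fm = assemble_feature_matrix(self._raw(rng))
        assert np.all(np.abs(fm.frame.mean()) < 1e-10)
        assert np.allclose(fm.frame.std(ddof=1), 1.0, atol=1e-10)
        # roster columns come first, in roster order
        assert fm.columns[:2] == ["PPh2Prob", "logDNase"][::-1] or fm.columns[:2] == ["logDNase", "PPh2Prob"]
        assert [c for c in fm.columns if c in TABLE_ROSTER] == [
            c for c in TABLE_ROSTER if c in fm.columns
        ]

    def test_scoring_is_idempotent_for_training_rows(self, rng):
        raw = self._raw(rng)
        fm = assemble_feature_matrix(raw)
        scored = assemble_feature_matrix(raw, stats=fm)
        pd.testing.assert_frame_equal(scored.frame, fm.frame)

    def test_scoring_shift_linearity(self, rng):
        raw = self._raw(rng)
        fm = assemble_feature_matrix(raw)
        delta = 0.7
        shifted = raw.copy()
        shifted["logDNase"] += delta
        scored = assemble_feature_matrix(shifted, stats=fm)
        expected = fm.frame["logDNase"] + delta / fm.sds["logDNase"]
        assert np.allclose(scored.frame["logDNase"], expected, atol=1e-10)

    def test_missing_value_names_snp_and_column(self, rng):
        raw = self._raw(rng)
        raw.loc["s3", "logDNase"] = np.nan
        with pytest.raises(ValueError, match="s3.*logDNase"):
            assemble_feature_matrix(raw)

    def test_unknown_stored_column_errors(self, rng):
        fm = assemble_feature_matrix(self._raw(rng))
        with pytest.raises(ValueError, match="absent"):
            assemble_feature_matrix(self._raw(rng).drop(columns=["extra_col"]), stats=fm)

    def test_constant_column_dropped_with_warning(self, rng):
        raw = self._raw(rng)
        raw["extra_col"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            fm = assemble_feature_matrix(raw)
        assert "extra_col" in fm.dropped and "extra_col" not in fm.columns
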