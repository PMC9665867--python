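import numpy as np
import pytest

from tdcrawl import (
    AlignmentFeaturizer,
    FeatureMatrix,
    FormatError,
    KmerTable,
    build_aligned_table,
    encode_features,
    fit_mlr_cv,
    synthetic_shape_table,
    zscore_filter,
)

SHAPES = synthetic_shape_table()


class TestZscoreFilter:
    def test_sample_sd_convention_pinned(self):
        # metrics {0,0,0,10}: mean 2.5, sample sd (n-1) = 5.0, so Z(10) = 1.5
        table = KmerTable(
            ("AAAAA", "CCCCC", "GGGGG", "TTTTT"),
            np.array([0.0, 0.0, 0.0, 10.0]),
        )
        kept = zscore_filter(table, threshold=1.4)
        assert kept.sequences == ("TTTTT",)
        with pytest.raises(FormatError, match="no k-mer passes"):
            zscore_filter(table, threshold=1.5)  # strict inequality

    def test_very_low_threshold_is_identity(self):
        table = KmerTable(
            ("AAAAA", "CCCCC", "GGGGG"), np.array([1.0, 2.0, 3.0])
        )
        kept = zscore_filter(table, threshold=float("-inf"))
        assert kept.sequences == table.sequences

    def test_constant_metric_fatal(self):
        table = KmerTable(("AAAAA", "CCCCC"), np.array([1.0, 1.0]))
        with pytest.raises(FormatError, match="degenerate"):
            zscore_filter(table)


def _aligned_block(rows):
    seqs, shifts, metrics = zip(*rows)
    table = KmerTable(seqs, np.array(metrics))
    return build_aligned_table(table, dict(zip(seqs, shifts)))


class TestEncodeFeatures:
    def test_dimensions_for_shift_zero_10mers(self):
        rows = [("ACGTACGTAC", 0, 1.0), ("TGCATGCATG", 0, 2.0)]
        fm = encode_features(_aligned_block(rows), SHAPES, (0, 0))
        # 4*10 one-hot + 2*(10-4) shape columns
        assert fm.X.shape == (2, 40 + 12)
        assert len(fm.feature_names) == 52

    def test_one_hot_blocks_sum_to_coverage(self):
        rows = [("ACGTA", 0, 1.0), ("CGTAC", 1, 2.0)]
        fm = encode_features(_aligned_block(rows), SHAPES, (0, 1))
        W = 6
        onehot = fm.X[:, : 4 * W].reshape(2, W, 4)
        sums = onehot.sum(axis=2)
        # rows are ordered by descending metric: CGTAC (shift 1) covers
        # window positions 1..5, ACGTA (shift 0) covers 0..4
        assert fm.sequences == ("CGTAC", "ACGTA")
        np.testing.assert_array_equal(sums[0], [0, 1, 1, 1, 1, 1])
        np.testing.assert_array_equal(sums[1], [1, 1, 1, 1, 1, 0])

    def test_single_row(self):
        fm = encode_features(
            _aligned_block([("ACGTACGTAC", 0, 1.0)]), SHAPES, (0, 0)
        )
        assert len(fm) == 1

    def test_rows_outside_window_excluded(self):
        rows = [("ACGTACGTAC", 0, 1.0), ("TGCATGCATG", 7, 2.0)]
        fm = encode_features(_aligned_block(rows), SHAPES, (-1, 1))
        assert fm.sequences == ("ACGTACGTAC",)

    def test_empty_window_fatal(self):
        rows = [("ACGTACGTAC", 0, 1.0)]
        with pytest.raises(FormatError, match="window"):
            encode_features(_aligned_block(rows), SHAPES, (2, -2))

    def test_row_order_permutation_permutes_rows(self):
        rows = [
            ("ACGTACGTAC", 0, 3.0),
            ("TGCATGCATG", 1, 2.0),
            ("GGGGGCCCCC", -1, 1.0),
        ]
        fm = encode_features(_aligned_block(rows), SHAPES, (-1, 1))
        # build_aligned_table orders rows by metric; re-encode from a
        # reordered block and match rows by sequence
        rows_rev = [rows[2], rows[0], rows[1]]
        fm2 = encode_features(_aligned_block(rows_rev), SHAPES, (-1, 1))
        idx = [fm2.sequences.index(s) for s in fm.sequences]
        np.testing.assert_allclose(fm.X, fm2.X[idx])


def _linear_problem(n, p, seed, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w = rng.normal(size=p)
    y = X @ w + noise * rng.normal(size=n)
    return FeatureMatrix(
        X=X, y=y, feature_names=tuple(f"f{i}" for i in range(p)),
        sequences=tuple(f"s{i}" for i in range(n)), window=(0, 0), k=5,
    )


class TestFitMlrCv:
    def test_perfect_linear_response_recovered(self):
        fm = _linear_problem(300, 20, seed=0)
        result = fit_mlr_cv(fm, folds=5, seed=1)
        assert result.median_r2 >= 0.999

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pure_noise_scores_near_zero(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(500, 25))
        y = rng.normal(size=500)
        fm = FeatureMatrix(
            X=X, y=y, feature_names=tuple(f"f{i}" for i in range(25)),
            sequences=tuple(f"s{i}" for i in range(500)), window=(0, 0), k=5,
        )
        result = fit_mlr_cv(fm, folds=5, seed=seed)
        assert result.median_r2 <= 0.05

    def test_duplicated_rows_stable(self):
        fm = _linear_problem(200, 15, seed=3, noise=0.5)
        doubled = FeatureMatrix(
            X=np.vstack([fm.X, fm.X]), y=np.concatenate([fm.y, fm.y]),
            feature_names=fm.feature_names,
            sequences=fm.sequences + tuple(f"{s}b" for s in fm.sequences),
            window=fm.window, k=fm.k,
        )
        r1 = fit_mlr_cv(fm, folds=5, seed=7)
        r2 = fit_mlr_cv(doubled, folds=5, seed=7)
        assert abs(r1.median_r2 - r2.median_r2) <= 0.02

    def test_identical_seed_identical_result(self):
        fm = _linear_problem(150, 10, seed=5, noise=1.0)
        r1 = fit_mlr_cv(fm, folds=5, seed=11)
        r2 = fit_mlr_cv(fm, folds=5, seed=11)
        assert r1.fold_r2 == r2.fold_r2

    def test_too_few_rows_fatal(self):
        fm = _linear_problem(8, 3, seed=0)
        with pytest.raises(FormatError, match="rows"):
            fit_mlr_cv(fm, folds=5)


class TestAlignmentFeaturizer:
    def test_transform_matches_function(self):
        rows = [("ACGTACGTAC", 0, 1.0), ("TGCATGCATG", 1, 2.0)]
        block = _aligned_block(rows)
        featurizer = AlignmentFeaturizer(shapes=SHAPES, window=(0, 1))
        featurizer.fit(block)
        X = featurizer.transform(block)
        fm = encode_features(block, SHAPES, (0, 1))
        np.testing.assert_allclose(X, fm.X)
        assert featurizer.feature_names_ == fm.feature_names
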