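"""Alignment-quality evaluation via regularized multiple linear regression.

The yardstick: if k-mers are aligned well, position-specific base identity
and local DNA shape should predict log enrichment, because substitutions
along a correctly registered binding site modulate affinity predictably.
The harness filters significantly enriched k-mers (Z-score on the log
enrichment), one-hot encodes bases over the aligned window, appends
pentamer shape features (minor groove width, electrostatic potential),
fits an elastic-net linear model under 5-fold cross-validation, and
reports the median held-out R^2.  A better alignment yields a higher
median R^2 on the same k-mers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import ElasticNetCV
from sklearn.metrics import r2_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .io_formats import ALPHABET, AlignedTable, FormatError, KmerTable
from .shape_features import ShapeTable, shape_profile

log = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: Elastic-net mixing grid searched on each training split.
L1_RATIOS = (0.1, 0.5, 0.9)
#: Length of the automatically scaled regularization path.
N_ALPHAS = 20


def zscore_filter(table: KmerTable, threshold: float = 2.0) -> KmerTable:
    """Keep k-mers whose metric exceeds the mean by ``threshold`` sample SDs.

    Z-scores use the sample standard deviation (n-1 denominator) over all
    input rows.  Intended for metrics already on the log-enrichment scale;
    no transformation is applied here.
    """
    m = table.metrics
    sd = m.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise FormatError("degenerate metric: standard deviation is 0")
    z = (m - m.mean()) / sd
    keep = z > threshold
    if not keep.any():
        raise FormatError(
            f"no k-mer passes the Z > {threshold} filter"
        )
    return table.subset(keep)


@dataclass(frozen=True)
class FeatureMatrix:
    """Design matrix for the evaluation regression.

    One row per k-mer; 4 one-hot columns per window position followed by
    one column per shape feature per interior window position.  Window
    positions a k-mer does not cover are all-zero in the one-hot block and
    column-mean imputed in the shape block.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    sequences: tuple[str, ...]
    window: tuple[int, int]
    k: int

    def __len__(self) -> int:
        return self.X.shape[0]


def encode_features(
    aligned: AlignedTable,
    shapes: ShapeTable,
    window: tuple[int, int],
) -> FeatureMatrix:
    """Encode aligned k-mers over an inclusive shift window.

    Rows with shifts outside ``window`` are excluded.  The padded window
    width is W = (hi - lo) + k; the one-hot block has 4W columns and each
    shape feature contributes W - 4 columns (interior positions with full
    pentamer context).  The response is the metric, taken as log
    enrichment.
    """
    lo, hi = window
    if lo > hi:
        raise FormatError(f"empty window ({lo}, {hi})")
    rows = [
        (seq, shift, metric)
        for seq, shift, metric in zip(
            aligned.kmers(), aligned.shifts, aligned.metrics
        )
        if lo <= shift <= hi
    ]
    if not rows:
        raise FormatError(f"no aligned k-mer has a shift in [{lo}, {hi}]")
    k = aligned.k
    W = (hi - lo) + k
    n = len(rows)
    features = shapes.features

    onehot = np.zeros((n, 4 * W))
    shape_blocks = {f: np.full((n, W - 4), np.nan) for f in features}
    for r, (seq, shift, _) in enumerate(rows):
        start = shift - lo
        for i, base in enumerate(seq):
            onehot[r, 4 * (start + i) + _BASE_INDEX[base]] = 1.0
        profile = shape_profile(seq, shapes)
        for f in features:
            # k-mer interior position i maps to window column start + 2 + i
            cols = start + np.arange(k - 4)
            shape_blocks[f][r, cols] = profile[f]

    # column-mean imputation for window positions a row does not cover;
    # all-missing columns become 0 (carry no information)
    for f in features:
        block = shape_blocks[f]
        observed = ~np.isnan(block)
        col_count = observed.sum(axis=0)
        col_mean = np.where(
            col_count > 0,
            np.nansum(block, axis=0) / np.maximum(col_count, 1),
            0.0,
        )
        idx = np.where(~observed)
        block[idx] = col_mean[idx[1]]

    X = np.hstack([onehot] + [shape_blocks[f] for f in features])
    names = tuple(
        f"s{lo + p}:{b}" for p in range(W) for b in ALPHABET
    ) + tuple(
        f"{f}:s{lo + 2 + p}" for f in features for p in range(W - 4)
    )
    return FeatureMatrix(
        X=X,
        y=np.array([m for _, _, m in rows]),
        feature_names=names,
        sequences=tuple(s for s, _, _ in rows),
        window=(lo, hi),
        k=k,
    )


@dataclass(frozen=True)
class CVResult:
    """Per-fold held-out R^2 values and their median."""

    fold_r2: tuple[float, ...]
    median_r2: float
    n: int

    def to_dict(self) -> dict:
        return {
            "fold_r2": list(self.fold_r2),
            "median_r2": self.median_r2,
            "n": self.n,
        }


def _make_model(l1_ratios, n_alphas) -> object:
    # `alphas` as an int requests an automatically scaled path of that
    # length (older scikit-learn spelled this `n_alphas`)
    try:
        enet = ElasticNetCV(
            l1_ratio=list(l1_ratios), alphas=n_alphas, cv=3, max_iter=5000
        )
    except TypeError:  # pragma: no cover
        enet = ElasticNetCV(
            l1_ratio=list(l1_ratios), n_alphas=n_alphas, cv=3, max_iter=5000
        )
    return make_pipeline(StandardScaler(), enet)


def fit_mlr_cv(
    features: FeatureMatrix,
    folds: int = 5,
    seed: int = 0,
    l1_ratios=L1_RATIOS,
    n_alphas: int = N_ALPHAS,
) -> CVResult:
    """Elastic-net linear regression under seeded k-fold cross-validation.

    Rows are shuffled once with the seeded RNG and split into ``folds``
    contiguous folds.  Per fold, predictors are standardized on the
    training split and the elastic-net hyperparameters (mixing ratio and
    penalty strength) are selected by inner 3-fold CV on the training
    split; R^2 is computed on the held-out fold against its own mean.
    """
    n = len(features)
    if n < 2 * folds:
        raise FormatError(
            f"need at least {2 * folds} rows for {folds}-fold CV, got {n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_idx = np.array_split(perm, folds)
    r2s: list[float] = []
    for held_out in fold_idx:
        train = np.setdiff1d(perm, held_out, assume_unique=True)
        model = _make_model(l1_ratios, n_alphas)
        model.fit(features.X[train], features.y[train])
        pred = model.predict(features.X[held_out])
        r2s.append(float(r2_score(features.y[held_out], pred)))
    return CVResult(tuple(r2s), float(np.median(r2s)), n)


class AlignmentFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer wrapping :func:`encode_features`.

    Parameters
    ----------
    shapes : ShapeTable
    window : (lo, hi) inclusive shift range
    """

    def __init__(
        self,
        shapes: ShapeTable | None = None,
        window: tuple[int, int] = (0, 0),
    ):
        self.shapes = shapes
        self.window = window

    def fit(self, X: AlignedTable, y=None) -> "AlignmentFeaturizer":
        if self.shapes is None:
            raise FormatError("AlignmentFeaturizer requires a shape table")
        fm = encode_features(X, self.shapes, tuple(self.window))
        self.feature_names_ = fm.feature_names
        return self

    def transform(self, X: AlignedTable) -> np.ndarray:
        fm = encode_features(X, self.shapes, tuple(self.window))
        return fm.X

    def encode(self, X: AlignedTable) -> FeatureMatrix:
        return encode_features(X, self.shapes, tuple(self.window))


class ElasticNetEvaluator(BaseEstimator):
    """Estimator wrapping :func:`fit_mlr_cv` plus a full-data final fit.

    ``cross_validate`` reports the per-fold and median held-out R^2 used to
    score alignments; ``fit``/``predict`` expose the underlying pipeline
    (standardizer + inner-CV elastic net) fitted on all rows.
    """

    def __init__(
        self,
        folds: int = 5,
        seed: int = 0,
        l1_ratios=L1_RATIOS,
        n_alphas: int = N_ALPHAS,
    ):
        self.folds = folds
        self.seed = seed
        self.l1_ratios = l1_ratios
        self.n_alphas = n_alphas

    def cross_validate(self, features: FeatureMatrix) -> CVResult:
        result = fit_mlr_cv(
            features,
            folds=self.folds,
            seed=self.seed,
            l1_ratios=self.l1_ratios,
            n_alphas=self.n_alphas,
        )
        self.cv_result_ = result
        return result

    def fit(self, X, y) -> "ElasticNetEvaluator":
        self.model_ = _make_model(self.l1_ratios, self.n_alphas)
        self.model_.fit(np.asarray(X), np.asarray(y))
        return self

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(np.asarray(X))
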