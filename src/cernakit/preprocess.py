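"""Expression filtering, median-of-ratios normalization, log transform.

Features are retained when their raw count exceeds ``min_count`` in at
least ``ceil(min_sample_frac * n_samples)`` samples. Per-sample size
factors follow the median-of-ratios estimator: each sample's factor is
the median, over features positive in every sample, of the ratio of its
count to the feature's geometric mean. The transform is a shifted log2
of size-factor-normalized counts — a variance-reasonable monotone
stand-in for regularized-log transforms whose empirical-Bayes shrinkage
is estimator-internal; the transform is pluggable via the ``kind``
argument should an alternative be needed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ValidationError


def filter_expressed(
    matrix: ExpressionMatrix,
    min_count: int = 5,
    min_sample_frac: float = 0.2,
) -> ExpressionMatrix:
    """Keep features expressed (count > min_count) in enough samples.

    "Enough" is at least ``ceil(min_sample_frac * n_samples)`` samples;
    the count comparison is strict. Feature order is preserved and the
    operation is idempotent.
    """
    if matrix.n_features == 0 or matrix.n_samples == 0:
        raise ValidationError("cannot filter an empty matrix")
    need = math.ceil(min_sample_frac * matrix.n_samples)
    expressed = (matrix.values > min_count).sum(axis=1) >= need
    return matrix.subset_features(matrix.feature_ids[expressed.to_numpy()])


def size_factors(matrix: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one positive real per sample.

    s_j = median over reference features i of k_ij / gm_i, where gm_i
    is the geometric mean of feature i across samples and the reference
    set is the features positive in every sample.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if values.shape[1] < 2:
        raise ValidationError("size factors need at least 2 samples")
    arr = values.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValidationError(
            "no feature positive in all samples; consider a pseudocount "
            "before normalization"
        )
    ref = arr[all_positive]
    log_gm = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_gm)
    return pd.Series(np.median(ratios, axis=0), index=values.columns,
                     name="size_factor")


def transform(
    matrix: ExpressionMatrix,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
    kind: str = "shifted_log",
) -> ExpressionMatrix:
    """log2(count / s_j + pseudocount), monotone in count per sample."""
    if kind != "shifted_log":
        raise ValueError(f"unknown transform kind {kind!r}")
    if factors is None:
        factors = size_factors(matrix)
    factors = factors.reindex(matrix.sample_ids)
    if factors.isna().any() or (factors <= 0).any():
        raise ValidationError("size factors must be positive for all samples")
    normed = matrix.values.to_numpy(dtype=float) / factors.to_numpy()
    out = pd.DataFrame(
        np.log2(normed + pseudocount),
        index=matrix.feature_ids,
        columns=matrix.sample_ids,
    )
    return ExpressionMatrix(
        out, matrix.feature_meta, matrix.sample_meta, transformed=True
    )
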