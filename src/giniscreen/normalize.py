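"""Quantile normalization and log2 transform of raw bead-array intensities.

Quantile normalization forces every array to share one intensity
distribution: the reference distribution is the per-rank mean of the
column-sorted values, and each column's values are replaced by the
reference value at their rank. Tied values within a column receive the
mean of the reference values across their tied rank span, which makes the
result deterministic and invariant to input row permutations.

The screen normalises on the raw scale first, then moves to log2 for the
additive linear model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, ValidationError

__all__ = ["quantile_normalize", "log2_transform"]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return a quantile-normalised copy of a raw intensity matrix.

    Every output column has the same multiset of values (up to the tie
    rule); probe and array ids are unchanged. Requires at least two arrays
    — with a single array there is nothing to normalise against.
    """
    if matrix.scale != "raw":
        raise ValidationError("quantile normalization expects a raw-scale matrix")
    if matrix.n_arrays < 2:
        raise ValidationError("quantile normalization needs >= 2 arrays")

    X = matrix.data.to_numpy(dtype=float)
    n, m = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    sorted_ = np.take_along_axis(X, order, axis=0)
    ref = sorted_.mean(axis=1)

    out = np.empty_like(X)
    for j in range(m):
        col_sorted = sorted_[:, j]
        # tied runs in the sorted column share the mean reference value
        starts = np.flatnonzero(np.r_[True, col_sorted[1:] != col_sorted[:-1]])
        counts = np.diff(np.r_[starts, n])
        group_means = np.add.reduceat(ref, starts) / counts
        out[order[:, j], j] = np.repeat(group_means, counts)

    data = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(data, matrix.genes, "raw")


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2 of a raw matrix; flips the scale flag."""
    if matrix.scale != "raw":
        raise ValidationError("log2_transform expects a raw-scale matrix")
    vals = matrix.data.to_numpy(dtype=float)
    if (vals <= 0).any():
        i, j = np.argwhere(vals <= 0)[0]
        raise ValidationError(
            f"non-positive intensity at probe {matrix.data.index[i]!r}, "
            f"array {matrix.data.columns[j]!r}"
        )
    data = pd.DataFrame(
        np.log2(vals), index=matrix.data.index, columns=matrix.data.columns
    )
    return ExpressionMatrix(data, matrix.genes, "log2")
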