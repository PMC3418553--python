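"""Detection-flag filtering, between-array quantile normalization, row z-scores.

All operations are pure: they return new :class:`ExpressionMatrix` objects
and never mutate their input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, MatrixError

#: Agilent-style detection labels used by the two array types.
MIRNA_FLAGS = frozenset({"IsGeneDetected", "WellAboveNeg"})
MRNA_FLAGS = frozenset({"IsFound", "IsWellAboveBG", "IsSaturated"})


@dataclass(frozen=True)
class FlagPolicy:
    """Keep a feature when >= ``min_fraction`` of samples carry all flags."""

    required_flags: frozenset = MIRNA_FLAGS
    min_fraction: float = 0.75

    def __post_init__(self):
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if not self.required_flags:
            raise ValueError("required_flags must be non-empty")


def filter_flags(matrix: ExpressionMatrix, policy: FlagPolicy) -> ExpressionMatrix:
    """Drop features detected in too few samples; order is preserved."""
    if matrix.flags is None:
        raise MatrixError("matrix carries no detection flags")
    cells = matrix.flags.map(lambda s: frozenset(str(s).split(";")) if s else frozenset())
    seen = frozenset().union(*cells.to_numpy().ravel())
    missing = policy.required_flags - seen
    if missing:
        raise MatrixError(f"flag label {sorted(missing)[0]!r} absent from matrix")
    ok = cells.map(lambda fs: policy.required_flags <= fs)
    frac = ok.mean(axis=1)
    keep = frac[frac >= policy.min_fraction].index
    return matrix.subset_features(keep)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Between-array quantile normalization.

    After the transform each column's sorted values equal the across-column
    mean of sorted values; ties within a column receive the mean of the
    quantile values their ranks span.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise MatrixError("quantile normalization needs >= 2 samples")
    if np.isnan(X).any():
        raise MatrixError("missing values; impute or drop upstream")
    mean_q = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = mean_q.copy()
        # average quantile values over runs of tied input values
        sorted_col = col[order]
        start = 0
        for i in range(1, len(col) + 1):
            if i == len(col) or sorted_col[i] != sorted_col[start]:
                if i - start > 1:
                    assigned[start:i] = mean_q[start:i].mean()
                start = i
        out[order, j] = assigned
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(values)


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-feature z-score (mean 0, sample SD 1) for heatmap export."""
    X = matrix.values.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise MatrixError(f"constant row: feature {matrix.values.index[bad[0]]!r}")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    values = pd.DataFrame(Z, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(values)
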