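"""Sign-constrained Pearson anti-correlation screening of DE feature pairs.

miRNAs repress their targets by mRNA degradation, so a genuine regulatory
pair should show opposite differential directions and a negative Pearson
correlation across the pooled tumor + normal samples. Every
(DE miRNA, DE mRNA) pair with opposite directions is evaluated; a pair
passes the screen when r < r_max (default -0.5) and p < p_max (default
0.05), and is retained when additionally its BH FDR over the whole
evaluated family is below fdr_max (default 0.3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .matrix import ExpressionMatrix, MatrixError

__all__ = ["pearson", "screen_pairs", "fdr_retain"]

PAIR_COLUMNS = [
    "mirna_id",
    "mrna_id",
    "r",
    "p_value",
    "fdr_bh",
    "mirna_direction",
    "mrna_direction",
    "passes_screen",
    "retained",
]


def pearson(x, y):
    """Pearson r and two-sided p via the t transform with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0:
        raise ValueError("zero variance in x")
    if sy == 0:
        raise ValueError("zero variance in y")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if 1.0 - abs(r) < 1e-12:  # exactly collinear up to round-off
        r = 1.0 if r > 0 else -1.0
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def screen_pairs(
    de_mirna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    r_max: float = -0.5,
    p_max: float = 0.05,
    enforce_direction: bool = True,
) -> pd.DataFrame:
    """Evaluate all called miRNA x called mRNA pairs (opposite directions).

    ``de_mirna``/``de_mrna`` are differential record frames (indexed by
    feature, with a ``direction`` column). Returns one row per evaluated
    pair with r, p and the screen flag; FDR is added by :func:`fdr_retain`.
    """
    if list(mirna_matrix.sample_ids) != list(mrna_matrix.sample_ids):
        raise MatrixError("miRNA and mRNA matrices must share the same sample set and order")

    mirnas = de_mirna.index[de_mirna["direction"] != "null"]
    mrnas = de_mrna.index[de_mrna["direction"] != "null"]
    rows = []
    if len(mirnas) and len(mrnas):
        X = mirna_matrix.values.loc[mirnas].to_numpy(dtype=float)
        Y = mrna_matrix.values.loc[mrnas].to_numpy(dtype=float)
        n = X.shape[1]
        Xc = X - X.mean(axis=1, keepdims=True)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        sx = np.sqrt((Xc * Xc).sum(axis=1))
        sy = np.sqrt((Yc * Yc).sum(axis=1))
        if np.any(sx == 0):
            raise MatrixError(f"zero variance in {mirnas[int(np.flatnonzero(sx == 0)[0])]!r}")
        if np.any(sy == 0):
            raise MatrixError(f"zero variance in {mrnas[int(np.flatnonzero(sy == 0)[0])]!r}")
        R = np.clip((Xc @ Yc.T) / np.outer(sx, sy), -1.0, 1.0)
        with np.errstate(divide="ignore"):
            T = R * np.sqrt((n - 2) / np.maximum(1 - R * R, 1e-300))
        P = 2 * stats.t.sf(np.abs(T), df=n - 2)
        P[np.abs(R) == 1.0] = 0.0

        dir_mi = de_mirna.loc[mirnas, "direction"]
        dir_mr = de_mrna.loc[mrnas, "direction"]
        for i, mi in enumerate(mirnas):
            for j, mr in enumerate(mrnas):
                opposite = dir_mi.iloc[i] != dir_mr.iloc[j]
                if enforce_direction and not opposite:
                    continue
                rows.append(
                    {
                        "mirna_id": mi,
                        "mrna_id": mr,
                        "r": R[i, j],
                        "p_value": P[i, j],
                        "mirna_direction": dir_mi.iloc[i],
                        "mrna_direction": dir_mr.iloc[j],
                        "passes_screen": bool(
                            (R[i, j] < r_max) and (P[i, j] < p_max) and opposite
                        ),
                    }
                )
    pairs = pd.DataFrame(rows, columns=[c for c in PAIR_COLUMNS if c not in ("fdr_bh", "retained")])
    pairs.attrs["r_max"] = r_max
    pairs.attrs["p_max"] = p_max
    return pairs


def fdr_retain(pairs: pd.DataFrame, fdr_max: float = 0.3) -> pd.DataFrame:
    """BH over the full evaluated family; retained = screen pass & FDR pass.

    Returns the input frame (copied) with ``fdr_bh`` and ``retained``
    columns, sorted by r ascending; filter on ``retained`` for the final
    screened set.
    """
    out = pairs.copy()
    if len(out) == 0:
        out["fdr_bh"] = pd.Series(dtype=float)
        out["retained"] = pd.Series(dtype=bool)
        return out
    out["fdr_bh"] = bh_adjust(out["p_value"].to_numpy())
    out["retained"] = out["passes_screen"] & (out["fdr_bh"] < fdr_max)
    out = out.sort_values("r", kind="mergesort").reset_index(drop=True)
    return out[PAIR_COLUMNS]


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)
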