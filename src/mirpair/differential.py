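"""Dual-gate differential expression for matched tumor/normal pairs.

A feature is called differentially expressed when it passes BOTH gates:

* paired Student t-test with Benjamini-Hochberg FDR below ``fdr_max``, and
* SAM (significance analysis of microarrays) q-value below ``q_max``.

The SAM branch is implemented for the paired design: the moderated
statistic is ``d = rbar / (s + s0)`` where ``rbar`` is the mean per-patient
log2 difference and ``s`` its standard error; the null distribution comes
from sign flips of the per-patient difference vectors (exhaustive when
``2**n_pairs`` is small, otherwise sampled); the false discovery rate at a
displacement threshold ``delta`` is the median number of falsely called
features across permutations divided by the observed call count, with the
null proportion pi0 fixed at 1 (conservative). A feature's q-value is the
minimum estimated FDR over all deltas at which it is called.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, MatrixError

__all__ = [
    "SamParams",
    "paired_t",
    "unpaired_t",
    "bh_adjust",
    "sam_statistic",
    "choose_s0",
    "sam_qvalues",
    "call_differential",
]


@dataclass
class SamParams:
    """Tuning knobs of the SAM permutation procedure.

    ``s0="auto"`` selects the fudge factor on a percentile grid of the
    per-feature standard errors (Tusher-style CV minimization);
    ``n_permutations=None`` means exhaustive sign flips when
    ``2**n_pairs <= exhaustive_cap``, else ``n_sampled`` seeded draws.
    """

    s0: float | str = "auto"
    n_permutations: int | None = None
    delta_grid: np.ndarray | None = None
    n_delta: int = 60
    seed: int = 0
    exhaustive_cap: int = 4096
    n_sampled: int = 1000

    def __post_init__(self):
        if isinstance(self.s0, str) and self.s0 != "auto":
            raise ValueError("s0 must be a nonnegative float or 'auto'")
        if not isinstance(self.s0, str) and self.s0 < 0:
            raise ValueError("s0 must be nonnegative")
        if self.delta_grid is not None:
            g = np.asarray(self.delta_grid, dtype=float)
            if g.ndim != 1 or np.any(np.diff(g) <= 0) or np.any(g < 0):
                raise ValueError("delta_grid must be strictly increasing and nonnegative")
            self.delta_grid = g


# ---------------------------------------------------------------------
# t statistics and BH

def _diff_stats(diffs: np.ndarray):
    """(mean, standard error) of per-patient differences, rows = features."""
    n = diffs.shape[1]
    if n < 2:
        raise MatrixError("paired statistics need >= 2 complete pairs")
    rbar = diffs.mean(axis=1)
    s = diffs.std(axis=1, ddof=1) / np.sqrt(n)
    return rbar, s


def paired_t(matrix: ExpressionMatrix, feature: str):
    """Paired t statistic and two-sided p for one feature.

    t = mean(d) / (sd(d)/sqrt(n)) with n-1 degrees of freedom, d being the
    tumor - normal log2 differences per patient.
    """
    diffs = matrix.paired_diffs().loc[[feature]].to_numpy()
    rbar, s = _diff_stats(diffs)
    if s[0] == 0:
        raise MatrixError(f"zero difference SD for feature {feature!r}")
    n = diffs.shape[1]
    t = rbar[0] / s[0]
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def unpaired_t(matrix: ExpressionMatrix, feature: str):
    """Two-sample Student t (equal variance) tumor vs normal."""
    row = matrix.values.loc[feature]
    t_vals = row[matrix.group_samples("tumor")].to_numpy()
    n_vals = row[matrix.group_samples("normal")].to_numpy()
    t, p = stats.ttest_ind(t_vals, n_vals, equal_var=True)
    return float(t), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------
# SAM

def sam_statistic(matrix: ExpressionMatrix, feature: str, s0: float) -> float:
    """d = rbar/(s + s0); with s0 = 0 this is exactly the paired t."""
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    diffs = matrix.paired_diffs().loc[[feature]].to_numpy()
    rbar, s = _diff_stats(diffs)
    denom = s[0] + s0
    if denom == 0:
        raise MatrixError(f"s + s0 = 0 for feature {feature!r}")
    return float(rbar[0] / denom)


def _choose_s0_from(rbar: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor minimizing the CV of window-wise MAD-scaled d.

    Candidates are percentiles 0, 5, ..., 100 of the s distribution;
    features are binned into s-quantile windows; for each candidate the
    coefficient of variation of the per-window MAD of d is evaluated and
    the smallest CV wins, ties going to the smallest candidate.
    """
    m = rbar.size
    candidates = np.percentile(s, np.arange(0, 101, 5))
    if np.any(s == 0):
        # zero-SE features make d undefined at s0 = 0; keep positive candidates
        candidates = candidates[candidates > 0]
        if candidates.size == 0:
            warnings.warn("all standard errors are zero; falling back to 1.0")
            return 1.0
    n_windows = int(max(1, min(100, m // 10)))
    edges = np.percentile(s, np.linspace(0, 100, n_windows + 1))
    window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)
    cvs = np.full(candidates.size, np.nan)
    for k, s0 in enumerate(candidates):
        d = rbar / (s + s0)
        mads = []
        for w in range(n_windows):
            dw = d[window == w]
            if dw.size:
                mads.append(np.median(np.abs(dw - np.median(dw))))
        mads = np.asarray(mads)
        mu = mads.mean()
        if mads.size and mu > 0:
            cvs[k] = mads.std(ddof=0) / mu
    if np.all(np.isnan(cvs)):
        warnings.warn("degenerate s distribution; falling back to median(s)")
        return float(np.median(s))
    best = np.nanmin(cvs)
    # smallest candidate among (near-)minimizers
    idx = int(np.flatnonzero(np.nan_to_num(cvs, nan=np.inf) <= best + 1e-12)[0])
    return float(candidates[idx])


def choose_s0(matrix: ExpressionMatrix) -> float:
    diffs = matrix.paired_diffs().to_numpy()
    rbar, s = _diff_stats(diffs)
    return _choose_s0_from(rbar, s)


def _sign_flips(n: int, params: SamParams) -> np.ndarray:
    """Permutation sign matrix (n_perms x n_pairs) of +/-1."""
    if params.n_permutations is None:
        exhaustive = 2**n <= params.exhaustive_cap
        n_perms = 2**n if exhaustive else params.n_sampled
    else:
        exhaustive = params.n_permutations == 2**n and 2**n <= params.exhaustive_cap
        n_perms = params.n_permutations
    if exhaustive:
        return np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    if n_perms < 10:
        raise ValueError("sampled mode needs >= 10 permutations")
    rng = np.random.default_rng(params.seed)
    return rng.choice((1.0, -1.0), size=(n_perms, n))


def _sam_core(diffs: np.ndarray, params: SamParams):
    """d statistics, expected order statistics, and per-delta FDR machinery."""
    rbar, s = _diff_stats(diffs)
    s0 = _choose_s0_from(rbar, s) if params.s0 == "auto" else float(params.s0)
    if np.any(s + s0 == 0):
        raise MatrixError("s + s0 = 0 for some feature; increase s0")
    d = rbar / (s + s0)

    signs = _sign_flips(diffs.shape[1], params)
    n = diffs.shape[1]
    # permuted d for every sign flip (vectorized over features)
    perm_d = np.empty((signs.shape[0], diffs.shape[0]))
    for b, sg in enumerate(signs):
        dp = diffs * sg[None, :]
        rb = dp.mean(axis=1)
        sb = dp.std(axis=1, ddof=1) / np.sqrt(n)
        perm_d[b] = rb / (sb + s0)
    perm_sorted = np.sort(perm_d, axis=1)
    dbar = perm_sorted.mean(axis=0)

    order = np.argsort(d, kind="mergesort")
    d_sorted = d[order]

    if params.delta_grid is not None:
        deltas = params.delta_grid
    else:
        deltas = np.linspace(0.0, float(np.max(np.abs(d))), params.n_delta)

    q = np.ones(d.size)
    for delta in deltas:
        disp = d_sorted - dbar
        up = np.flatnonzero(disp >= delta)
        low = np.flatnonzero(-disp >= delta)
        cut_up = d_sorted[up[0]] if up.size else np.inf
        cut_low = d_sorted[low[-1]] if low.size else -np.inf
        if cut_low >= cut_up:  # degenerate: everything called
            called = np.ones(d.size, dtype=bool)
        else:
            called = (d >= cut_up) | (d <= cut_low)
        n_called = int(called.sum())
        if n_called == 0:
            continue
        false_counts = ((perm_d >= cut_up) | (perm_d <= cut_low)).sum(axis=1)
        fdr = min(1.0, float(np.median(false_counts)) / n_called)
        q[called] = np.minimum(q[called], fdr)
    return d, q, s0


def sam_qvalues(matrix: ExpressionMatrix, params: SamParams | None = None) -> pd.DataFrame:
    """Per-feature SAM d statistic and q-value.

    Returns a DataFrame indexed by feature with columns ``d_stat``,
    ``q_value`` and the attribute ``s0`` stored in ``DataFrame.attrs``.
    """
    params = params or SamParams()
    diffs = matrix.paired_diffs().to_numpy()
    d, q, s0 = _sam_core(diffs, params)
    out = pd.DataFrame({"d_stat": d, "q_value": q}, index=matrix.values.index)
    out.attrs["s0"] = s0
    return out


# ---------------------------------------------------------------------
# calling

def call_differential(
    matrix: ExpressionMatrix,
    fdr_max: float = 0.05,
    q_max: float = 0.05,
    params: SamParams | None = None,
    paired: bool = True,
) -> pd.DataFrame:
    """Full differential record per feature, stable input order.

    Columns: mean_diff, t_stat, p_value, fdr_bh, d_stat, q_value,
    direction (``up``/``down``/``null``). Direction is non-null exactly
    when ``fdr_bh < fdr_max`` and ``q_value < q_max``.
    """
    params = params or SamParams()
    if paired:
        diffs = matrix.paired_diffs().to_numpy()
        rbar, s = _diff_stats(diffs)
        n = diffs.shape[1]
        # constant nonzero differences (possible after quantile
        # normalization of small matrices) degenerate to t = +/-inf, p = 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(s > 0, rbar / s, np.sign(rbar) * np.inf)
        t = np.where((s == 0) & (rbar == 0), 0.0, t)
        p = np.where(np.isinf(t), 0.0, 2 * stats.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df=n - 1))
        p = np.where((s == 0) & (rbar == 0), 1.0, p)
        mean_diff = rbar
    else:
        tv = matrix.values[matrix.group_samples("tumor")].to_numpy()
        nv = matrix.values[matrix.group_samples("normal")].to_numpy()
        t, p = stats.ttest_ind(tv, nv, axis=1, equal_var=True)
        mean_diff = tv.mean(axis=1) - nv.mean(axis=1)
        diffs = None

    fdr = bh_adjust(p)
    if paired:
        d, q, s0 = _sam_core(diffs, params)
    else:
        # SAM branch always runs on the paired design; unpaired calling
        # falls back to the t gate alone.
        d, q, s0 = t, np.zeros_like(t), 0.0

    passed = (fdr < fdr_max) & (q < q_max)
    direction = np.where(~passed, "null", np.where(mean_diff > 0, "up", "down"))
    out = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "t_stat": t,
            "p_value": p,
            "fdr_bh": fdr,
            "d_stat": d,
            "q_value": q,
            "direction": direction,
        },
        index=matrix.values.index,
    )
    out.index.name = "feature_id"
    out.attrs["s0"] = s0
    return out


def write_differential(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t")
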