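import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mirpair.differential import (
    SamParams,
    bh_adjust,
    call_differential,
    choose_s0,
    paired_t,
    sam_qvalues,
    sam_statistic,
)
from mirpair.matrix import MatrixError

from conftest import make_matrix, matrix_from_diffs


class TestPairedT:
    def test_hand_formula_example(self):
        m = matrix_from_diffs([[1.0, 2.0, 3.0]])
        t, p = paired_t(m, "f000")
        assert t == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(3.4641016, df=2), rel=1e-6)

    def test_symmetric_differences_give_t_zero(self):
        m = matrix_from_diffs([[-1.0, 1.0]])
        t, p = paired_t(m, "f000")
        assert t == 0.0 and p == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_ttest_rel(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(4, 10))
        m = make_matrix(vals)
        tumor = vals[:, 0::2]
        normal = vals[:, 1::2]
        for i, f in enumerate(m.feature_ids):
            t, p = paired_t(m, f)
            ref = stats.ttest_rel(tumor[i], normal[i])
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_difference_sd_errors(self):
        m = matrix_from_diffs([[2.0, 2.0, 2.0]])
        with pytest.raises(MatrixError, match="zero difference SD"):
            paired_t(m, "f000")


class TestBH:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.04, 0.03, 0.02]), [0.04] * 4)

    def test_single_p_unchanged_and_all_ones(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30), st.randoms(use_true_random=False))
    def test_permutation_invariant(self, ps, rnd):
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        base = bh_adjust(ps)
        shuffled = bh_adjust([ps[i] for i in perm])
        np.testing.assert_allclose([shuffled[perm.index(i)] for i in range(len(ps))], base)


class TestSamStatistic:
    def test_s0_zero_reduces_to_paired_t(self):
        m = matrix_from_diffs([[1.0, 2.0, 3.0]])
        assert sam_statistic(m, "f000", 0.0) == pytest.approx(paired_t(m, "f000")[0], abs=1e-14)

    @pytest.mark.parametrize("seed", range(3))
    def test_s0_zero_identity_random(self, seed):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.normal(size=(6, 8)))
        for f in m.feature_ids:
            assert sam_statistic(m, f, 0.0) == pytest.approx(paired_t(m, f)[0], abs=1e-12)

    def test_hand_oracle_with_fudge(self):
        diffs = np.array([1.0, 2.0, 3.0])
        m = matrix_from_diffs([diffs])
        s = diffs.std(ddof=1) / np.sqrt(3)
        assert sam_statistic(m, "f000", 0.5) == pytest.approx(diffs.mean() / (s + 0.5), abs=1e-12)

    def test_monotone_decreasing_in_s0(self):
        m = matrix_from_diffs([[1.0, 2.0, 3.0]])
        ds = [sam_statistic(m, "f000", s0) for s0 in (0.0, 0.5, 1.0, 5.0, 50.0)]
        assert all(a > b > 0 for a, b in zip(ds, ds[1:]))


class TestChooseS0:
    def test_deterministic(self, small_matrix):
        assert choose_s0(small_matrix) == choose_s0(small_matrix)

    def test_heteroscedastic_s_reduces_cv(self):
        rng = np.random.default_rng(5)
        # modest location effects + tiny residual SD -> wild d at s0=0
        sds = np.concatenate([np.full(50, 0.01), np.full(50, 1.0)])
        mu = rng.normal(0, 0.3, size=100)
        diffs = mu[:, None] + rng.normal(0, sds[:, None], size=(100, 6))
        m = matrix_from_diffs(diffs)
        s0 = choose_s0(m)
        assert s0 > 0

        def cv_of_d(s0_val):
            d = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / np.sqrt(6) + s0_val)
            s = diffs.std(axis=1, ddof=1) / np.sqrt(6)
            edges = np.percentile(s, np.linspace(0, 100, 11))
            mads = []
            for lo, hi in zip(edges, edges[1:]):
                dw = d[(s >= lo) & (s <= hi)]
                if dw.size:
                    mads.append(np.median(np.abs(dw - np.median(dw))))
            mads = np.array(mads)
            return mads.std() / mads.mean()

        assert cv_of_d(s0) < cv_of_d(0.0)


# ---------------------------------------------------------------------
# independent brute-force SAM oracle (naive enumeration over sign flips)

def sam_oracle(diffs, s0, deltas):
    m, n = diffs.shape

    def dstat(vec):
        rbar = sum(vec) / n
        var = sum((v - rbar) ** 2 for v in vec) / (n - 1)
        return rbar / ((var**0.5) / (n**0.5) + s0)

    d = np.array([dstat(list(diffs[i])) for i in range(m)])
    perm = []
    for signs in itertools.product((1.0, -1.0), repeat=n):
        perm.append([dstat([diffs[i][j] * signs[j] for j in range(n)]) for i in range(m)])
    perm = np.array(perm)
    dbar = np.sort(perm, axis=1).mean(axis=0)
    d_sorted = np.sort(d)
    q = np.ones(m)
    for delta in deltas:
        ups = [i for i in range(m) if d_sorted[i] - dbar[i] >= delta]
        lows = [i for i in range(m) if dbar[i] - d_sorted[i] >= delta]
        cut_up = d_sorted[ups[0]] if ups else np.inf
        cut_low = d_sorted[lows[-1]] if lows else -np.inf
        if cut_low >= cut_up:
            called = np.ones(m, dtype=bool)
        else:
            called = (d >= cut_up) | (d <= cut_low)
        nc = int(called.sum())
        if nc == 0:
            continue
        false_med = np.median(
            [int(((perm[b] >= cut_up) | (perm[b] <= cut_low)).sum()) for b in range(len(perm))]
        )
        q[called] = np.minimum(q[called], min(1.0, false_med / nc))
    return d, q


class TestSamQvalues:
    def test_exhaustive_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        diffs = rng.normal(0, 1, size=(20, 4))
        diffs[:4] += 2.5  # a few real effects
        m = matrix_from_diffs(diffs)
        deltas = np.linspace(0.0, 6.0, 25)
        params = SamParams(s0=0.2, delta_grid=deltas)
        res = sam_qvalues(m, params)
        d_o, q_o = sam_oracle(diffs, 0.2, deltas)
        np.testing.assert_allclose(res["d_stat"].to_numpy(), d_o, rtol=0, atol=1e-12)
        np.testing.assert_allclose(res["q_value"].to_numpy(), q_o, rtol=0, atol=1e-12)

    def test_null_data_rarely_called(self):
        frac = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m = matrix_from_diffs(rng.normal(0, 1, size=(50, 6)))
            res = sam_qvalues(m, SamParams(s0=0.1, seed=seed))
            frac.append((res["q_value"] < 0.05).mean())
        assert np.median(frac) <= 0.05

    def test_largest_d_has_minimal_q(self):
        rng = np.random.default_rng(1)
        diffs = rng.normal(0, 1, size=(30, 5))
        diffs[0] = 8.0 + rng.normal(0, 0.1, 5)  # dominant effect
        m = matrix_from_diffs(diffs)
        res = sam_qvalues(m, SamParams(s0=0.2))
        assert res["q_value"].iloc[0] == res["q_value"].min()

    def test_sampled_mode_needs_enough_permutations(self):
        m = matrix_from_diffs(np.random.default_rng(0).normal(size=(10, 4)))
        with pytest.raises(ValueError, match=">= 10"):
            sam_qvalues(m, SamParams(n_permutations=5, exhaustive_cap=2))


class TestCallDifferential:
    def test_dual_gate_requires_both(self):
        rng = np.random.default_rng(9)
        diffs = rng.normal(0, 0.3, size=(30, 8))
        diffs[0] += 3.0
        m = matrix_from_diffs(diffs)
        rec = call_differential(m)
        called = rec[rec["direction"] != "null"]
        assert (called["fdr_bh"] < 0.05).all() and (called["q_value"] < 0.05).all()
        assert "f000" in called.index and called.loc["f000", "direction"] == "up"

    def test_calling_is_monotone_in_thresholds(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(0, 1, size=(40, 8))
        diffs[:5] += 2.0
        m = matrix_from_diffs(diffs)
        loose = call_differential(m, fdr_max=0.1, q_max=0.1)
        tight = call_differential(m, fdr_max=0.01, q_max=0.01)
        loose_called = set(loose.index[loose["direction"] != "null"])
        tight_called = set(tight.index[tight["direction"] != "null"])
        assert tight_called <= loose_called

    def test_direction_follows_sign_of_mean_diff(self):
        rng = np.random.default_rng(4)
        diffs = rng.normal(0, 0.2, size=(20, 8))
        diffs[0] += 2.0
        diffs[1] -= 2.0
        m = matrix_from_diffs(diffs)
        rec = call_differential(m)
        assert rec.loc["f000", "direction"] == "up"
        assert rec.loc["f001", "direction"] == "down"
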