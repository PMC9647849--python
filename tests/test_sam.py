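import itertools
import math

import numpy as np
import pytest

from tmtde.sam import SamConfig, sam_qvalues, sam_statistic, ttest_fc, volcano_boundary


class TestTtestFc:
    def test_textbook_instance(self, two_group_zmatrix):
        # A=(1,2,3), B=(4,5,6): mean diff -3, pooled SD 1, t = -3/sqrt(2/3)
        m = two_group_zmatrix([[1.0, 2.0, 3.0]], [[4.0, 5.0, 6.0]])
        res = ttest_fc(m, ("PSP", "HC"))
        assert res["log2fc"].iloc[0] == pytest.approx(-3.0)
        assert res["tstat"].iloc[0] == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), rel=1e-9)
        # df = 4, two-sided p from the t distribution
        from scipy import stats
        assert res["pvalue"].iloc[0] == pytest.approx(
            2 * stats.t.sf(3.0 / math.sqrt(2.0 / 3.0), 4), rel=1e-9)

    def test_identical_groups_are_null(self, two_group_zmatrix):
        m = two_group_zmatrix([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        res = ttest_fc(m, ("PSP", "HC"))
        assert res["tstat"].iloc[0] == 0.0
        assert res["log2fc"].iloc[0] == 0.0

    def test_swapping_groups_negates(self, two_group_zmatrix):
        rng = np.random.default_rng(1)
        m = two_group_zmatrix(rng.normal(size=(6, 5)), rng.normal(size=(6, 5)))
        ab = ttest_fc(m, ("PSP", "HC"))
        ba = ttest_fc(m, ("HC", "PSP"))
        np.testing.assert_allclose(ab["tstat"], -ba["tstat"])
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"])
        np.testing.assert_allclose(ab["pvalue"], ba["pvalue"])

    def test_zero_variance_row_warns(self, two_group_zmatrix):
        m = two_group_zmatrix([[1.0, 1.0, 1.0]], [[1.0, 1.0, 1.0]])
        with pytest.warns(UserWarning, match="zero pooled variance"):
            res = ttest_fc(m, ("PSP", "HC"))
        assert res["tstat"].iloc[0] == 0.0 and res["pvalue"].iloc[0] == 1.0


class TestSamStatistic:
    def test_s0_zero_equals_t(self):
        rng = np.random.default_rng(2)
        diff, se = rng.normal(size=50), np.abs(rng.normal(size=50)) + 0.1
        np.testing.assert_allclose(sam_statistic(diff, se, 0.0), diff / se)

    def test_large_s0_shrinks_to_zero(self):
        diff, se = np.array([3.0, -2.0]), np.array([0.5, 0.5])
        assert np.abs(sam_statistic(diff, se, 1e9)).max() < 1e-8

    def test_direct_formula(self):
        # independent evaluation of d = diff / (se + s0)
        diff, se, s0 = np.array([1.2, -0.4, 0.0]), np.array([0.3, 0.2, 0.5]), 0.1
        expected = [1.2 / 0.4, -0.4 / 0.3, 0.0]
        np.testing.assert_allclose(sam_statistic(diff, se, s0), expected)


def brute_force_sam_q(X, na, s0=0.0):
    """Independent oracle: exhaustive relabeling FDR with plain loops.

    For every |d| threshold (each observed |d|), FDR = median over ALL
    C(n, na) relabelings of #{|d*| >= thr}, divided by #{|d| >= thr};
    q(protein) = min FDR over thresholds at or below its own |d|.
    """
    n = X.shape[1]

    def dscores(cols_a):
        cols_b = [j for j in range(n) if j not in cols_a]
        out = []
        for row in X:
            a, b = row[list(cols_a)], row[cols_b]
            sp2 = (a.var(ddof=1) * (len(a) - 1) + b.var(ddof=1) * (len(b) - 1)) / (n - 2)
            se = math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
            out.append((a.mean() - b.mean()) / (se + s0))
        return np.array(out)

    d_obs = np.abs(dscores(tuple(range(na))))
    all_d = [np.abs(dscores(c)) for c in itertools.combinations(range(n), na)]
    fdrs = {}
    for thr in d_obs:
        n_obs = int((d_obs >= thr).sum())
        counts = [int((dd >= thr).sum()) for dd in all_d]
        fdrs[thr] = min(1.0, float(np.median(counts)) / n_obs)
    qs = []
    for d in d_obs:
        qs.append(min(f for t, f in fdrs.items() if t <= d))
    return np.array(qs)


class TestSamQvalues:
    def test_matches_exhaustive_enumeration_oracle(self, two_group_zmatrix):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(8, 3))
        B = rng.normal(size=(8, 3))
        A[0] += 4.0  # one clear hit
        m = two_group_zmatrix(A, B)
        cfg = SamConfig(s0=0.0, n_permutations=10_000, seed=0)  # > C(6,3): enumerate
        with pytest.warns(UserWarning, match="distinct relabelings"):
            res = sam_qvalues(m, ("PSP", "HC"), cfg)
        expected = brute_force_sam_q(np.concatenate([A, B], axis=1), 3, s0=0.0)
        np.testing.assert_allclose(res["q_sam"].to_numpy(), expected, atol=1e-12)

    def test_q_monotone_in_abs_d(self, two_group_zmatrix):
        rng = np.random.default_rng(8)
        m = two_group_zmatrix(rng.normal(size=(100, 8)), rng.normal(size=(100, 8)))
        res = sam_qvalues(m, ("PSP", "HC"), SamConfig(n_permutations=50, seed=1))
        srt = res.reindex(res["dstat"].abs().sort_values(ascending=False).index)
        assert (np.diff(srt["q_sam"].to_numpy()) >= -1e-12).all()
        assert res["q_sam"].between(0, 1).all()

    def test_deterministic_given_seed(self, two_group_zmatrix):
        rng = np.random.default_rng(9)
        m = two_group_zmatrix(rng.normal(size=(40, 6)), rng.normal(size=(40, 6)))
        cfg = SamConfig(n_permutations=60, seed=5)
        r1 = sam_qvalues(m, ("PSP", "HC"), cfg)
        r2 = sam_qvalues(m, ("PSP", "HC"), cfg)
        np.testing.assert_array_equal(r1["q_sam"], r2["q_sam"])

    def test_extreme_planted_effect_is_called(self, two_group_zmatrix):
        rng = np.random.default_rng(10)
        A = rng.normal(size=(1, 15))
        B = rng.normal(size=(1, 15))
        A += 5.0  # |effect| = 5 residual SDs
        m = two_group_zmatrix(A, B, n_extra_rows=300, seed=11)
        res = sam_qvalues(m, ("PSP", "HC"), SamConfig(n_permutations=250, seed=2))
        assert res["q_sam"].iloc[0] < 0.05


def test_volcano_boundary_separates_calls(two_group_zmatrix):
    rng = np.random.default_rng(12)
    A = rng.normal(size=(30, 15))
    A[:10] += 3.0
    m = two_group_zmatrix(A, rng.normal(size=(30, 15)))
    cfg = SamConfig(n_permutations=100, seed=3)
    res = sam_qvalues(m, ("PSP", "HC"), cfg)
    curve = volcano_boundary(res, cfg)
    assert not curve.empty
    assert set(curve["side"]) <= {"up", "down"}
    assert (curve["neg_log10_p"] >= 0).all()
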