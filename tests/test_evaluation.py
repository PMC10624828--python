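"""Agreement statistics: MAE, Bland-Altman, ICC, Wilcoxon, sens/spec, Dice/IoU."""

import itertools
import math

import numpy as np
import pytest

from fetalbiom.evaluation import (
    PairedSeries,
    bland_altman,
    dice_iou,
    icc,
    mae,
    paired_wilcoxon,
    sens_spec,
)
from fetalbiom.imaging_io import LabelMask


def series(a, b):
    return PairedSeries(np.asarray(a, float), np.asarray(b, float))


class TestMae:
    def test_identical_series_zero(self):
        m, sd = mae(series([1, 2, 3], [1, 2, 3]))
        assert (m, sd) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        m, _ = mae(series([1, 2, 3], [2, 2, 2]))
        assert m == pytest.approx(2.0 / 3.0)

    def test_pair_permutation_invariance(self):
        a, b = [3.0, 7.0, 1.0, 9.0], [2.5, 8.0, 1.5, 7.0]
        m1, s1 = mae(series(a, b))
        m2, s2 = mae(series(a[::-1], b[::-1]))
        assert (m1, s1) == (m2, s2)


class TestBlandAltman:
    def test_identical_series_degenerate_limits(self):
        st = bland_altman(series([1, 2, 3], [1, 2, 3]))
        assert st.bias == 0.0 and st.loa_low == 0.0 and st.loa_high == 0.0

    def test_hand_calculated_three_pairs(self):
        # d = (1, -1, 1): bias 1/3, sd = 2/sqrt(3)
        st = bland_altman(series([10, 20, 30], [9, 21, 29]))
        assert st.bias == pytest.approx(1.0 / 3.0)
        assert st.sd_diff == pytest.approx(2.0 / math.sqrt(3.0))
        assert st.loa_low == pytest.approx(1.0 / 3.0 - 1.96 * 2.0 / math.sqrt(3.0))
        assert st.loa_high == pytest.approx(1.0 / 3.0 + 1.96 * 2.0 / math.sqrt(3.0))

    def test_swapping_series_negates_bias_and_mirrors_limits(self):
        a, b = [10.0, 20.0, 30.0, 40.0], [9.0, 22.0, 29.0, 41.0]
        st = bland_altman(series(a, b))
        sw = bland_altman(series(b, a))
        assert sw.bias == pytest.approx(-st.bias)
        assert sw.loa_low == pytest.approx(-st.loa_high)
        assert sw.loa_high == pytest.approx(-st.loa_low)

    def test_percentage_mode_matches_absolute_when_pair_means_are_100(self):
        a = [101.0, 99.0, 102.0, 97.0]
        b = [99.0, 101.0, 98.0, 103.0]  # every pair mean exactly 100
        st_abs = bland_altman(series(a, b), percentage=False)
        st_pct = bland_altman(series(a, b), percentage=True)
        assert st_pct.bias == pytest.approx(st_abs.bias)
        assert st_pct.loa_high == pytest.approx(st_abs.loa_high)

    def test_zero_pair_mean_rejected_with_ids(self):
        with pytest.raises(ValueError, match="zero pair mean"):
            bland_altman(
                PairedSeries(np.array([1.0, -2.0]), np.array([1.0, 2.0]),
                             ("s1", "s2")),
                percentage=True,
            )


class TestIcc:
    def test_identical_raters_unity(self):
        assert icc(series([1, 2, 3, 4], [1, 2, 3, 4])) == pytest.approx(1.0)

    def test_identical_subjects_nonpositive(self):
        assert icc(series([5, 5, 5, 5], [6, 6, 6, 6])) <= 0.0

    def test_monte_carlo_recovery_of_variance_ratio(self):
        # sigma_b^2 = 3, sigma_w^2 = 1 -> ICC = 0.75
        rng = np.random.default_rng(7)
        n = 500
        subj = rng.normal(0.0, math.sqrt(3.0), n)
        a = subj + rng.normal(0.0, 1.0, n)
        b = subj + rng.normal(0.0, 1.0, n)
        assert icc(series(a, b)) == pytest.approx(0.75, abs=0.05)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        a = rng.normal(10, 2, 30)
        b = a + rng.normal(0, 1, 30)
        s = series(a, b)
        df = pd.DataFrame({
            "subject": list(range(30)) * 2,
            "rater": ["a"] * 30 + ["b"] * 30,
            "score": np.concatenate([a, b]),
        })
        res = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        icc1 = float(res.loc[res["Type"].isin(["ICC1", "ICC(1,1)"]), "ICC"].iloc[0])
        icc2 = float(res.loc[res["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0])
        assert icc(s) == pytest.approx(icc1, abs=1e-9)
        assert icc(s, model="two-way") == pytest.approx(icc2, abs=1e-6)

    def test_zero_variance_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="zero total variance"):
            assert math.isnan(icc(series([2, 2, 2], [2, 2, 2])))


def enumeration_wilcoxon_p(diffs):
    """Oracle: exact two-sided p over all 2^n sign assignments (mid-ranks)."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    ws = np.asarray(ws)
    n_tot = len(ws)
    p_low = (ws <= w_obs + 1e-9).sum() / n_tot
    p_high = (ws >= w_obs - 1e-9).sum() / n_tot
    return min(1.0, 2.0 * min(p_low, p_high))


class TestPairedWilcoxon:
    def test_symmetric_differences_no_shift(self):
        a = [10, 11, 12, 13, 14, 15]
        b = [11, 10, 13, 12, 15, 14]  # paired +/-1 differences
        res = paired_wilcoxon(series(a, b))
        assert res.method == "exact"
        assert res.pvalue > 0.5

    def test_all_positive_n10_p_is_2_over_1024(self):
        a = np.arange(10.0) + 1.0
        res = paired_wilcoxon(series(a + 1.0, a))
        assert res.statistic == 55.0
        assert res.pvalue == pytest.approx(2.0 / 1024.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_enumeration_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        d = np.round(rng.normal(0, 2, n), 1)
        d[d == 0] = 0.5
        a = rng.normal(50, 5, n)
        res = paired_wilcoxon(series(a + d, a))
        assert res.method == "exact"
        # enumerate over the realized differences (float addition can
        # perturb planted ties)
        assert res.pvalue == pytest.approx(
            enumeration_wilcoxon_p((a + d) - a), abs=1e-12
        )

    def test_ties_in_absolute_differences_use_midranks(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, -2.0, 3.0, 3.0])
        a = np.full(8, 20.0)
        res = paired_wilcoxon(series(a + d, a))
        assert res.pvalue == pytest.approx(enumeration_wilcoxon_p(d), abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        res = paired_wilcoxon(series([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]))
        assert res.method == "degenerate"
        assert res.pvalue == 1.0

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10, 1, 40)
        b = a + rng.normal(0.3, 0.5, 40)
        res = paired_wilcoxon(series(a, b))
        assert res.method == "normal"
        from scipy.stats import wilcoxon as scipy_wilcoxon

        ref = scipy_wilcoxon(a, b, zero_method="wilcox", correction=True,
                             method="approx")
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)


class TestSensSpec:
    def test_perfect_prediction(self):
        r = sens_spec([True, False, True], [True, False, True])
        assert (r.sensitivity, r.specificity) == (1.0, 1.0)

    def test_hand_counts(self):
        truth = [True] * 7 + [False] * 14
        pred = [True] * 6 + [False] * 1 + [True] * 2 + [False] * 12
        r = sens_spec(pred, truth)
        assert r.sensitivity == pytest.approx(6 / 7)
        assert r.specificity == pytest.approx(12 / 14)
        assert (r.tp, r.fn, r.fp, r.tn) == (6, 1, 2, 12)

    def test_absent_positive_class_undefined_with_reason(self):
        r = sens_spec([False, True], [False, False])
        assert r.sensitivity is None
        assert "sensitivity undefined" in r.reason


class TestDiceIou:
    def _mask(self, grid):
        return LabelMask(np.asarray(grid, dtype=bool), "brain")

    def test_identical_masks(self):
        g = np.zeros((10, 10), bool)
        g[2:6, 2:6] = True
        assert dice_iou(self._mask(g), self._mask(g)) == (1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool); a[0:2, 0:2] = True
        b = np.zeros((10, 10), bool); b[5:7, 5:7] = True
        assert dice_iou(self._mask(a), self._mask(b)) == (0.0, 0.0)

    def test_half_overlap_hand_arithmetic(self):
        a = np.zeros((20, 20), bool); a[0:10, 0:10] = True        # 100 px
        b = np.zeros((20, 20), bool); b[5:15, 0:10] = True        # 100 px, 50 shared
        d, i = dice_iou(self._mask(a), self._mask(b))
        assert d == pytest.approx(0.5)
        assert i == pytest.approx(1.0 / 3.0)

    def test_dice_iou_identity_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random((16, 16)) > 0.5
            b = rng.random((16, 16)) > 0.5
            d, i = dice_iou(self._mask(a), self._mask(b))
            assert d >= i
            assert d == pytest.approx(2.0 * i / (1.0 + i), abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            dice_iou(self._mask(np.zeros((4, 4), bool)),
                     self._mask(np.zeros((5, 5), bool)))
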