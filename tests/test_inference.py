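"""Within-subject ANOVA, GG correction, t-tests, gain-slope regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gazeshift import (
    SlopeFit,
    fit_gain_slopes,
    paired_t,
    rm_anova,
    slopes_vs_zero,
)
from oracles import contrast_anova, longhand_2x2


def _long(arr, factors):
    """subjects x levels... array -> long DataFrame."""
    n = arr.shape[0]
    rows = []
    for s in range(n):
        for idx in np.ndindex(*arr.shape[1:]):
            row = {"subject": f"s{s}", "value": arr[(s,) + idx]}
            for f, i in zip(factors, idx):
                row[f] = f"l{i}"
            rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_two_level_factor_df_with_24_subjects(self):
        rng = np.random.default_rng(0)
        data = _long(rng.normal(size=(24, 2)), ["target"])
        res = rm_anova(data, dv="value", within=["target"])
        eff = res["target"]
        assert (eff.df_num, eff.df_den) == (1.0, 23.0)
        assert eff.gg_epsilon == 1.0

    def test_no_effect_gives_zero_F(self):
        # identical values across conditions within each subject
        arr = np.tile(np.arange(6, dtype=float)[:, None, None], (1, 2, 2))
        res = rm_anova(_long(arr, ["a", "b"]), dv="value", within=["a", "b"])
        for eff in res:
            assert eff.F == 0.0
            assert eff.p == 1.0
            assert not eff.degenerate

    def test_matches_longhand_2x2_oracle(self):
        rng = np.random.default_rng(42)
        arr = rng.normal(size=(6, 2, 2))
        res = rm_anova(_long(arr, ["a", "b"]), dv="value", within=["a", "b"])
        oracle = longhand_2x2(arr)
        for name, key in [("a", "A"), ("b", "B"), ("a x b", "A x B")]:
            ss_eff, ss_err, f = oracle[key]
            eff = res[name]
            assert eff.F == pytest.approx(f, abs=1e-10)
            assert eff.eta_sq == pytest.approx(
                ss_eff / (ss_eff + ss_err), abs=1e-10)

    @pytest.mark.parametrize("shape", [(6, 2, 2), (8, 2, 2, 2), (7, 3, 2)])
    def test_matches_contrast_projection_oracle(self, shape):
        rng = np.random.default_rng(hash(shape) % 2**31)
        arr = rng.normal(size=shape)
        factors = list("abc")[: len(shape) - 1]
        res = rm_anova(_long(arr, factors), dv="value", within=factors)
        oracle = contrast_anova(arr)
        for eff_axes, (ss_eff, ss_err, f) in oracle.items():
            name = " x ".join(factors[ax - 1] for ax in eff_axes)
            assert res[name].F == pytest.approx(f, abs=1e-10)

    def test_F_equals_squared_paired_t_for_two_levels(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            arr = rng.normal(size=(10, 2))
            res = rm_anova(_long(arr, ["cond"]), dv="value", within=["cond"])
            tt = paired_t(arr[:, 0], arr[:, 1])
            assert res["cond"].F == pytest.approx(tt.t ** 2, rel=1e-10)
            assert res["cond"].p == pytest.approx(tt.p, rel=1e-9)

    def test_gg_epsilon_bounds_and_correction(self):
        rng = np.random.default_rng(3)
        # strongly non-spherical 3-level data: epsilon must shrink the dfs
        base = rng.normal(size=(12, 1))
        arr = np.concatenate(
            [base + rng.normal(0, 0.01, (12, 1)),
             base + rng.normal(0, 0.01, (12, 1)),
             rng.normal(0, 5, (12, 1))], axis=1)
        res = rm_anova(_long(arr, ["g"]), dv="value", within=["g"])
        eff = res["g"]
        assert 0.5 <= eff.gg_epsilon < 1.0
        assert eff.df_num == pytest.approx(2 * eff.gg_epsilon)
        assert eff.df_den == pytest.approx(22 * eff.gg_epsilon)

    def test_matches_pingouin_one_factor(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        arr = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        data = _long(arr, ["g"])
        res = rm_anova(data, dv="value", within=["g"])["g"]
        pg = pingouin.rm_anova(data=data, dv="value", within="g",
                               subject="subject", correction=True,
                               effsize="np2").iloc[0]
        assert res.F == pytest.approx(pg["F"], rel=1e-8)
        assert res.gg_epsilon == pytest.approx(pg["eps"], rel=1e-6)
        assert res.p == pytest.approx(pg["p_GG_corr"], rel=1e-6)
        assert res.eta_sq == pytest.approx(pg["np2"], rel=1e-8)

    def test_matches_statsmodels_three_factor_F(self):
        anova_rm = pytest.importorskip("statsmodels.stats.anova")
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(9, 2, 2, 2))
        data = _long(arr, ["a", "b", "c"])
        res = rm_anova(data, dv="value", within=["a", "b", "c"])
        sm = anova_rm.AnovaRM(data, depvar="value", subject="subject",
                              within=["a", "b", "c"]).fit().anova_table
        mapping = {"a": "a", "b": "b", "c": "c", "a:b": "a x b",
                   "a:c": "a x c", "b:c": "b x c", "a:b:c": "a x b x c"}
        for sm_name, our_name in mapping.items():
            assert res[our_name].F == pytest.approx(
                sm.loc[sm_name, "F Value"], rel=1e-8)
            assert res[our_name].df_num == pytest.approx(
                sm.loc[sm_name, "Num DF"])

    def test_unbalanced_table_errors(self):
        data = _long(np.zeros((4, 2)), ["cond"]).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova(data, dv="value", within=["cond"])

    def test_zero_error_variance_degenerate(self):
        arr = np.zeros((5, 2))
        arr[:, 1] = 1.0  # identical shift for every subject
        res = rm_anova(_long(arr, ["cond"]), dv="value", within=["cond"])
        eff = res["cond"]
        assert eff.degenerate
        assert np.isinf(eff.F) and eff.p == 0.0


class TestPairedT:
    def test_identical_samples(self):
        a = np.arange(6, dtype=float)
        res = paired_t(a, a)
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_longhand_one_sample_arithmetic(self):
        d = np.array([1.0, 2.0, 3.0, 2.0, 1.0, 3.0])
        res = paired_t(d, np.zeros(6))
        mean = d.sum() / 6
        sd = np.sqrt(((d - mean) ** 2).sum() / 5)
        assert res.t == pytest.approx(mean / (sd / np.sqrt(6)), abs=1e-12)
        assert res.df_num == 5

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(size=10)
        raw = paired_t(a, b)
        corrected = paired_t(a, b, correction_m=2)
        assert corrected.p == pytest.approx(min(2 * raw.p, 1.0))
        assert paired_t(a, b, correction_m=10**6).p == 1.0

    def test_multiplication_rule_example(self):
        # p = 0.004 under m = 2 becomes 0.008
        assert min(0.004 * 2, 1.0) == pytest.approx(0.008)
        rng = np.random.default_rng(2)
        a = rng.normal(size=8)
        b = a + 1.0 + rng.normal(0, 0.3, 8)
        assert paired_t(a, b, correction_m=2).p == pytest.approx(
            2 * paired_t(a, b).p)

    def test_unpaired_variant(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=12), rng.normal(1.0, 1.0, size=15)
        res = paired_t(a, b, paired=False)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.df_num == 25


class TestGainSlopes:
    GAINS = (1.0, 1.15, 1.3)

    def _frame(self, pha_by_subject):
        rows = []
        for subj, phas in pha_by_subject.items():
            for g, p in zip(self.GAINS, phas):
                rows.append({"subject": subj, "gain": g, "pha": p})
        return pd.DataFrame(rows)

    def test_exact_three_point_line(self):
        fits = fit_gain_slopes(self._frame({"s0": (0.0, 0.15, 0.3)}),
                               pha_col="pha")
        assert fits[0].slope == pytest.approx(1.0, abs=1e-12)

    def test_flat_phas_give_zero_slope(self):
        fits = fit_gain_slopes(self._frame({"s0": (0.2, 0.2, 0.2)}),
                               pha_col="pha")
        assert fits[0].slope == pytest.approx(0.0, abs=1e-12)

    def test_requires_exactly_three_gains(self):
        frame = self._frame({"s0": (0.0, 0.1, 0.2)}).iloc[:-1]
        with pytest.raises(ValueError):
            fit_gain_slopes(frame, pha_col="pha")

    def test_simulated_slope_recovery(self):
        rng = np.random.default_rng(25)
        true_slope = 0.5
        data = {}
        for s in range(25):
            intercept = rng.normal(0, 0.1)
            data[f"s{s:02d}"] = tuple(
                intercept + true_slope * g + rng.normal(0, 0.2)
                for g in self.GAINS)
        fits = fit_gain_slopes(self._frame(data), pha_col="pha")
        slopes = np.array([f.slope for f in fits])
        se = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean() - true_slope) < 3 * se


class TestSlopesVsZero:
    def test_all_zero_slopes(self):
        res = slopes_vs_zero([SlopeFit("s", 0.0, 0.0)] * 5)
        assert res.t == 0.0 and res.degenerate

    def test_df_with_25_slopes(self):
        rng = np.random.default_rng(4)
        res = slopes_vs_zero(list(rng.normal(size=25)))
        assert res.df_num == 24

    def test_longhand_arithmetic(self):
        res = slopes_vs_zero([0.1, 0.2, 0.3], tails="two")
        assert res.t == pytest.approx(0.2 / (0.1 / np.sqrt(3)), abs=1e-12)
        assert res.t == pytest.approx(3.4641, abs=1e-4)

    def test_one_tailed_convention_matches_reported_probability(self):
        # t(24) = 2.03 corresponds to p = 0.027 one-tailed (0.054 two-tailed)
        assert sps.t.sf(2.03, 24) == pytest.approx(0.027, abs=5e-4)
        rng = np.random.default_rng(14)
        vals = list(rng.normal(0.3, 0.5, size=25))
        one = slopes_vs_zero(vals, tails="one")
        two = slopes_vs_zero(vals, tails="two")
        assert one.t == pytest.approx(two.t)
        assert two.p == pytest.approx(2 * one.p) or one.p > 0.5
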