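"""Pooled estimators, heterogeneity, and effect-model selection."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.meta_analysis import combine_effects

import snpmeta as sm

TOY_TABLES = [(4, 7, 5, 3), (2, 9, 8, 6), (5, 5, 4, 9)]


def hand_oracle(tables):
    """Spreadsheet-style recomputation: MH OR, RBG variance, Q, DL tau^2."""
    R = S = sPR = sMIX = sQS = 0.0
    ys, ws = [], []
    for a, b, c, d in tables:
        n = a + b + c + d
        r, s = a * d / n, b * c / n
        p, q = (a + d) / n, (b + c) / n
        R, S = R + r, S + s
        sPR += p * r
        sMIX += p * s + q * r
        sQS += q * s
        ys.append(math.log(a * d / (b * c)))
        ws.append(1.0 / (1 / a + 1 / b + 1 / c + 1 / d))
    or_mh = R / S
    var_mh = sPR / (2 * R * R) + sMIX / (2 * R * S) + sQS / (2 * S * S)
    ybar = sum(w * y for w, y in zip(ws, ys)) / sum(ws)
    Q = sum(w * (y - ybar) ** 2 for w, y in zip(ws, ys))
    C = sum(ws) - sum(w * w for w in ws) / sum(ws)
    tau2 = max(0.0, (Q - (len(tables) - 1)) / C)
    return or_mh, var_mh, Q, tau2


def effects_of(tables):
    return [sm.study_effect(sm.TwoByTwo(*t), study_id=str(i)) for i, t in enumerate(tables)]


class TestMantelHaenszel:
    def test_matches_hand_oracle_to_six_decimals(self):
        pool = sm.pool_mh([sm.TwoByTwo(*t) for t in TOY_TABLES])
        het = sm.heterogeneity(effects_of(TOY_TABLES))
        or_mh, var_mh, Q, tau2 = hand_oracle(TOY_TABLES)
        assert pool.pooled_or == pytest.approx(or_mh, abs=1e-6)
        assert pool.se == pytest.approx(math.sqrt(var_mh), abs=1e-6)
        assert het.Q == pytest.approx(Q, abs=1e-6)
        assert het.tau2 == pytest.approx(tau2, abs=1e-6)

    def test_matches_statsmodels_stratified_table(self, corpus):
        model = sm.GenotypeMetaAnalysis(corpus, "rs3731217", "allelic")
        arr = np.array(
            [[[t.case_exposed, t.ctrl_exposed], [t.case_unexposed, t.ctrl_unexposed]]
             for t in model.tables], dtype=float
        ).transpose(1, 2, 0)
        ref = StratifiedTable(arr)
        pool = sm.pool_mh(model.tables)
        assert pool.pooled_or == pytest.approx(ref.oddsratio_pooled, rel=1e-12)
        assert pool.se == pytest.approx(ref.logodds_pooled_se, rel=1e-12)

    def test_single_table_reduces_to_crude_or(self):
        t = sm.TwoByTwo(44, 336, 45, 319)
        pool = sm.pool_mh([t])
        assert pool.pooled_or == pytest.approx((44 * 319) / (336 * 45), rel=1e-12)
        assert pool.single_study

    def test_duplication_leaves_point_estimate_fixed_and_shrinks_ci(self):
        t = sm.TwoByTwo(44, 336, 45, 319)
        one, two = sm.pool_mh([t]), sm.pool_mh([t, t])
        assert two.pooled_or == pytest.approx(one.pooled_or, rel=1e-12)
        assert (two.ci_high - two.ci_low) < (one.ci_high - one.ci_low)

    def test_duplicating_every_study_preserves_estimate(self, corpus):
        tables = sm.GenotypeMetaAnalysis(corpus, "rs3731249", "allelic").tables
        assert sm.pool_mh(tables + tables).pooled_or == pytest.approx(
            sm.pool_mh(tables).pooled_or, rel=1e-12)

    def test_all_degenerate_errors(self):
        with pytest.raises(ValueError, match="no non-degenerate"):
            sm.pool_mh([sm.TwoByTwo(0, 10, 0, 10)])


class TestDerSimonianLaird:
    def test_two_effect_hand_arithmetic(self):
        # w = 100 each; Q = 100*0.25 + 100*0.25 = 50; C = 200 - 20000/200 = 100
        effs = [sm.EffectEstimate("a", "x", 0.0, 0.1),
                sm.EffectEstimate("b", "x", 1.0, 0.1)]
        het = sm.heterogeneity(effs)
        assert het.Q == pytest.approx(50.0, abs=1e-10)
        assert het.tau2 == pytest.approx(0.49, abs=1e-10)
        assert het.I2 == pytest.approx(98.0, abs=1e-9)

    def test_identical_effects_collapse_to_fixed_pooling(self):
        effs = [sm.EffectEstimate(s, "x", 0.3, se) for s, se in
                [("a", 0.1), ("b", 0.2), ("c", 0.15)]]
        het = sm.heterogeneity(effs)
        assert het.Q == pytest.approx(0.0, abs=1e-12)
        assert het.tau2 == 0.0 and het.I2 == 0.0
        dl, iv = sm.pool_dl(effs), sm.pool_iv(effs)
        assert dl.pooled_or == pytest.approx(iv.pooled_or, rel=1e-12)
        assert dl.se == pytest.approx(iv.se, rel=1e-12)

    def test_matches_statsmodels_combine_effects(self, corpus):
        effs = sm.GenotypeMetaAnalysis(corpus, "rs3731217", "heterozygote").effects
        ref = combine_effects(np.array([e.log_or for e in effs]),
                              np.array([e.variance for e in effs]), method_re="dl")
        het = sm.heterogeneity(effs)
        assert het.Q == pytest.approx(ref.q, rel=1e-9)
        assert het.tau2 == pytest.approx(max(0.0, ref.tau2), rel=1e-9)
        assert sm.pool_dl(effs).pooled_or == pytest.approx(
            math.exp(ref.mean_effect_re), rel=1e-9)

    def test_requires_two_effects(self):
        with pytest.raises(ValueError, match="k >= 2"):
            sm.pool_dl([sm.EffectEstimate("a", "x", 0.0, 0.1)])

    @given(shift=st.floats(-3, 3), seed=st.integers(0, 10_000))
    def test_q_invariant_under_common_shift(self, shift, seed):
        rng = np.random.default_rng(seed)
        effs = [sm.EffectEstimate(str(i), "x", float(rng.normal()), float(rng.uniform(0.05, 1)))
                for i in range(5)]
        shifted = [sm.EffectEstimate(e.study_id, e.model, e.log_or + shift, e.se)
                   for e in effs]
        assert sm.heterogeneity(shifted).Q == pytest.approx(
            sm.heterogeneity(effs).Q, rel=1e-8, abs=1e-8)


class TestModelSelection:
    @pytest.mark.parametrize("i2,ph,expected", [
        (42.76, 0.045, "random"),   # significant Q despite I2 < 50
        (31.62, 0.175, "fixed"),
        (0.0, 1.0, "fixed"),
        (70.0, 0.20, "random"),     # I2 alone can trigger
    ])
    def test_rule(self, i2, ph, expected):
        h = sm.HeterogeneityResult(Q=1, df=1, P_H=ph, I2=i2, tau2=0)
        assert sm.select_model(h) == expected

    def test_thresholds_configurable(self):
        h = sm.HeterogeneityResult(Q=1, df=1, P_H=0.2, I2=40, tau2=0)
        assert sm.select_model(h, i2_threshold=30) == "random"
        assert sm.select_model(h, ph_threshold=0.3) == "random"
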