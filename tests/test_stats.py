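"""Repeated-measures ANOVA, Holm correction, circular statistics."""

import numpy as np
import pandas as pd
import pytest

from synergait import stats as ss
from oracles import hk_oracle, rm_anova_f_oracle


def _long(table, levels, subject_prefix="S"):
    rows = []
    for li, lv in enumerate(levels):
        for si, v in enumerate(table[li]):
            rows.append({"subject": f"{subject_prefix}{si}", "tp": lv,
                         "y": float(v)})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_f_matches_sums_of_squares_oracle(self):
        table = np.array([[5.0, 6.0, 7.0, 8.0],
                          [6.0, 7.0, 9.0, 9.0],
                          [7.0, 8.0, 9.0, 11.0]])
        df = _long(table, ["Pre", "Post1", "Post2"])
        res = ss.rm_anova(df, "y", "tp", "subject")
        assert res[0].F == pytest.approx(rm_anova_f_oracle(table), abs=1e-8)

    def test_identical_levels_give_zero_f(self):
        table = np.tile([4.0, 5.5, 6.0, 7.2], (3, 1))
        res = ss.rm_anova(_long(table, ["a", "b", "c"]), "y", "tp", "subject")
        assert res[0].F == pytest.approx(0.0, abs=1e-20)
        assert res[0].p == pytest.approx(1.0)

    def test_two_level_factor_never_corrected(self, rng):
        table = rng.random((2, 8))
        res = ss.rm_anova(_long(table, ["x", "y"]), "y", "tp", "subject")
        assert not res[0].gg_applied
        assert res[0].df_num == 1

    def test_missing_cells_rejected(self):
        df = _long(np.random.default_rng(0).random((3, 4)), ["a", "b", "c"])
        with pytest.raises(ValueError, match="missing"):
            ss.rm_anova(df.iloc[:-1], "y", "tp", "subject")

    def test_two_way_effect_names(self, rng):
        rows = []
        for s in range(6):
            for tp in ("Pre", "Post1", "Post2"):
                for c in ("normal", "narrow"):
                    rows.append({"subject": f"S{s}", "tp": tp, "cond": c,
                                 "y": rng.normal()})
        res = ss.rm_anova(pd.DataFrame(rows), "y", ["tp", "cond"], "subject")
        assert [r.effect for r in res] == ["tp", "cond", "tp * cond"]

    def test_gg_correction_scales_df(self, rng):
        # strong sphericity violation: one level has inflated variance and
        # correlations differ across level pairs
        n = 12
        base = rng.normal(size=n)
        table = np.stack([base + 0.01 * rng.normal(size=n),
                          base + 0.01 * rng.normal(size=n),
                          3.0 * rng.normal(size=n)])
        res = ss.rm_anova(_long(table, ["a", "b", "c"]), "y", "tp", "subject")
        r = res[0]
        if r.gg_applied:  # Mauchly significant for this construction
            assert r.epsilon is not None and r.epsilon < 1.0
            assert r.df_num == pytest.approx(2 * r.epsilon)


class TestHolm:
    def test_step_down_example(self):
        np.testing.assert_allclose(ss.holm_posthoc([0.01, 0.04, 0.03]),
                                   [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ss.holm_posthoc([0.2]), [0.2])

    def test_equal_ps_scale_by_m(self):
        np.testing.assert_allclose(ss.holm_posthoc([0.02] * 4), [0.08] * 4)

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.uniform(0.001, 1.0, size=10)
        adj = ss.holm_posthoc(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ss.holm_posthoc([0.5, 1.2])
        with pytest.raises(ValueError):
            ss.holm_posthoc([])


class TestCircMean:
    def test_simple_cases(self):
        assert ss.circ_mean([0.0, 0.0]) == pytest.approx(0.0)
        assert ss.circ_mean([np.pi / 2 - 0.1, np.pi / 2 + 0.1]) == pytest.approx(np.pi / 2)

    def test_wraps_into_range(self):
        assert 0 <= ss.circ_mean([-0.1, -0.2]) < 2 * np.pi

    def test_zero_resultant_undefined(self):
        with pytest.raises(ValueError, match="resultant"):
            ss.circ_mean([0.0, np.pi])


class TestHarrisonKanji:
    def _design(self, rng, n=20, kappa=50.0, shift=0.0):
        ang, fa, fb = [], [], []
        for tp in ("Pre", "Post1", "Post2"):
            for cond in ("normal", "narrow"):
                mu = 1.0 + (shift if cond == "narrow" else 0.0)
                a = rng.vonmises(mu, kappa, n) % (2 * np.pi)
                ang.extend(a); fa.extend([tp] * n); fb.extend([cond] * n)
        return np.array(ang), np.array(fa), np.array(fb)

    def test_all_equal_angles_null(self):
        ang = np.full(24, 1.0)
        fa = np.repeat(["a", "b", "c"], 8)
        fb = np.tile(np.repeat(["x", "y"], 4), 3)
        res = ss.circ_anova2(ang, fa, fb)
        for r in res:
            assert r.F == pytest.approx(0.0, abs=1e-6)
            assert r.p == pytest.approx(1.0)

    def test_shifted_condition_detected(self, rng):
        ang, fa, fb = self._design(rng, shift=np.pi / 4)
        res = {r.effect: r for r in ss.circ_anova2(ang, fa, fb)}
        assert res["B"].p < 0.01          # condition effect present
        assert res["A"].p > 0.05          # no training effect imposed

    def test_matches_equation_oracle_on_12_angle_fixture(self):
        # fixed 12-angle fixture: 2 x 2 design, 3 per cell
        ang = np.array([0.1, 0.2, 0.15, 0.8, 0.9, 0.85,
                        0.3, 0.25, 0.35, 1.1, 1.0, 1.05])
        fa = np.repeat(["a1", "a2"], 6)
        fb = np.tile(np.repeat(["b1", "b2"], 3), 2)
        mine = {r.effect: r for r in ss.circ_anova2(ang, fa, fb)}
        ref = hk_oracle(ang, fa, fb)
        for eff in ("A", "B", "A * B"):
            assert mine[eff].F == pytest.approx(ref[eff][0], rel=1e-10)
            assert mine[eff].p == pytest.approx(ref[eff][1], rel=1e-10)

    def test_matches_oracle_low_concentration(self, rng):
        # dispersed angles exercise the chi-squared branch
        ang = rng.uniform(0, 2 * np.pi, size=24)
        fa = np.repeat(["a1", "a2"], 12)
        fb = np.tile(np.repeat(["b1", "b2"], 6), 2)
        mine = {r.effect: r for r in ss.circ_anova2(ang, fa, fb)}
        ref = hk_oracle(ang, fa, fb)
        for eff in ("A", "B", "A * B"):
            assert mine[eff].F == pytest.approx(ref[eff][0], rel=1e-10)

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError, match="balanced|cell"):
            ss.circ_anova2([0.1, 0.2, 0.3], ["a", "a", "b"], ["x", "y", "x"])

    def test_degenerate_cell_warns(self):
        # each 4-angle cell is {0, pi, 0, pi}: exactly zero resultant
        ang = np.array([0.0, np.pi] * 8)
        fa = np.repeat(["a1", "a2"], 8)
        fb = np.tile(np.repeat(["b1", "b2"], 4), 2)
        with pytest.warns(UserWarning, match="resultant"):
            ss.circ_anova2(ang, fa, fb)
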