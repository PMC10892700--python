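import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from ergofield import stats
from ergofield.io import ValidationError


def long_table(rng, n_subj, levels, effect=0.0, factor="cond"):
    rows = []
    for s in range(n_subj):
        base = rng.normal()
        for i, lev in enumerate(levels):
            rows.append({"worker_id": f"s{s}", factor: lev,
                         "value": base + effect * i + rng.normal()})
    return pd.DataFrame(rows)


class TestShapiroScreen:
    def test_normal_samples_usually_pass(self):
        passes = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(24)
            if stats.shapiro_screen(x)["normal"]:
                passes += 1
        assert passes >= 90

    def test_constant_vector_non_computable(self):
        res = stats.shapiro_screen(np.full(24, 3.0))
        assert res["normal"] is None and np.isnan(res["W"])

    def test_two_point_sample_rejected(self):
        x = np.array([0.0] * 12 + [5.0] * 12)
        assert stats.shapiro_screen(x)["p"] < 0.05

    def test_small_n_is_error(self):
        with pytest.raises(ValidationError):
            stats.shapiro_screen(np.array([1.0, 2.0]))


class TestRmAnovaOneFactor:
    def test_identical_conditions_give_f_zero_p_one(self, rng):
        vals = rng.normal(size=8)
        df = pd.DataFrame(
            [{"worker_id": i, "cond": c, "value": vals[i]}
             for i in range(8) for c in ("a", "b")])
        res = stats.rm_anova(df, within=["cond"], subject="worker_id")
        assert res.F[0] == 0.0 and res.p_gg[0] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_two_levels_equal_squared_paired_t(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        df = long_table(rng, n, ["a", "b"], effect=0.4)
        res = stats.rm_anova(df, within=["cond"], subject="worker_id")
        wide = df.pivot(index="worker_id", columns="cond", values="value")
        t, p = sps.ttest_rel(wide["a"], wide["b"])
        assert res.F[0] == pytest.approx(t ** 2, rel=1e-9)
        assert res.p_gg[0] == pytest.approx(p, rel=1e-9)
        assert res.epsilon_gg[0] == 1.0

    def test_three_levels_match_pingouin(self, rng):
        df = long_table(rng, 12, ["a", "b", "c"], effect=0.5)
        res = stats.rm_anova(df, within=["cond"], subject="worker_id")
        ref = pg.rm_anova(data=df, dv="value", within="cond",
                          subject="worker_id", correction=True, detailed=True)
        assert res.F[0] == pytest.approx(ref.F[0], rel=1e-9)
        assert res.epsilon_gg[0] == pytest.approx(ref.eps[0], rel=1e-9)
        assert res.p_gg[0] == pytest.approx(ref.p_GG_corr[0], rel=1e-9)
        assert res.ss_effect[0] == pytest.approx(ref.SS[0], rel=1e-9)
        assert res.ss_error[0] == pytest.approx(ref.SS[1], rel=1e-9)

    def test_missing_cell_rejected(self, rng):
        df = long_table(rng, 6, ["a", "b"]).iloc[:-1]
        with pytest.raises(ValidationError, match="missing cell"):
            stats.rm_anova(df, within=["cond"], subject="worker_id")

    def test_partial_eta_sq_consistent_with_f(self, rng):
        df = long_table(rng, 10, ["a", "b", "c"], effect=0.3)
        res = stats.rm_anova(df, within=["cond"], subject="worker_id")
        f, d1, d2 = res.F[0], res.df_num[0], res.df_den[0]
        assert res.partial_eta_sq[0] == pytest.approx(
            f * d1 / (f * d1 + d2), rel=1e-9)


class TestRmAnovaTwoFactor:
    @staticmethod
    def brute_force_ss(Y):
        """Direct cell-means decomposition for an n x a x b table."""
        n, a, b = Y.shape
        g = Y.mean()
        ss = {}
        ss["subj"] = a * b * ((Y.mean(axis=(1, 2)) - g) ** 2).sum()
        ss["A"] = n * b * ((Y.mean(axis=(0, 2)) - g) ** 2).sum()
        ss["B"] = n * a * ((Y.mean(axis=(0, 1)) - g) ** 2).sum()
        AB = Y.mean(axis=0)
        ss["AB"] = n * ((AB - Y.mean(axis=(0, 2))[:, None]
                         - Y.mean(axis=(0, 1))[None, :] + g) ** 2).sum()
        AS = Y.mean(axis=2)
        ss["errA"] = b * ((AS - Y.mean(axis=(0, 2))[None, :]
                           - Y.mean(axis=(1, 2))[:, None] + g) ** 2).sum()
        BS = Y.mean(axis=1)
        ss["errB"] = a * ((BS - Y.mean(axis=(0, 1))[None, :]
                           - Y.mean(axis=(1, 2))[:, None] + g) ** 2).sum()
        ss["total"] = ((Y - g) ** 2).sum()
        ss["errAB"] = (ss["total"] - ss["subj"] - ss["A"] - ss["errA"]
                       - ss["B"] - ss["errB"] - ss["AB"])
        return ss

    def test_2x2_ss_match_brute_force(self, rng):
        n = 6
        Y = rng.normal(size=(n, 2, 2)) + np.array([[0, 0.5], [0.2, 1.0]])
        rows = [{"worker_id": s, "a": f"a{i}", "b": f"b{j}",
                 "value": Y[s, i, j]}
                for s in range(n) for i in range(2) for j in range(2)]
        res = stats.rm_anova(pd.DataFrame(rows), within=["a", "b"],
                             subject="worker_id")
        ss = self.brute_force_ss(Y)
        by_effect = dict(zip(res.effect, zip(res.ss_effect, res.ss_error)))
        assert by_effect["a"][0] == pytest.approx(ss["A"], rel=1e-9)
        assert by_effect["a"][1] == pytest.approx(ss["errA"], rel=1e-9)
        assert by_effect["b"][0] == pytest.approx(ss["B"], rel=1e-9)
        assert by_effect["b"][1] == pytest.approx(ss["errB"], rel=1e-9)
        assert by_effect["a * b"][0] == pytest.approx(ss["AB"], rel=1e-9)
        assert by_effect["a * b"][1] == pytest.approx(ss["errAB"], rel=1e-8)
        total = (res.ss_effect.sum() + res.ss_error.sum()
                 + res.attrs["ss_subjects"])
        assert total == pytest.approx(res.attrs["ss_total"], rel=1e-9)

    def test_2x3_matches_pingouin(self, rng):
        rows = [{"worker_id": s, "a": av, "b": bv,
                 "value": rng.normal() + 0.4 * (av == "a2") + 0.2 * int(bv[1])}
                for s in range(10) for av in ("a1", "a2")
                for bv in ("b1", "b2", "b3")]
        df = pd.DataFrame(rows)
        res = stats.rm_anova(df, within=["a", "b"], subject="worker_id")
        ref = pg.rm_anova(data=df, dv="value", within=["a", "b"],
                          subject="worker_id", correction=True, detailed=True)
        for eff in ("a", "b", "a * b"):
            mine = res[res.effect == eff].iloc[0]
            theirs = ref[ref.Source == eff].iloc[0]
            assert mine.F == pytest.approx(theirs.F, rel=1e-9)
            assert mine.p_unc == pytest.approx(theirs.p_unc, rel=1e-9)
            assert mine.p_gg == pytest.approx(theirs.p_GG_corr, rel=1e-9)
            assert mine.epsilon_gg == pytest.approx(theirs.eps, rel=1e-9)


class TestBonferroni:
    def test_single_pair_equals_unadjusted_paired_t(self, rng):
        df = long_table(rng, 15, ["a", "b"], effect=0.5)
        out = stats.bonferroni_posthoc(df, within="cond",
                                       pairs=[("a", "b")])
        wide = df.pivot(index="worker_id", columns="cond", values="value")
        d = wide["a"] - wide["b"]
        t, p = sps.ttest_rel(wide["a"], wide["b"])
        ci = sps.t.interval(0.95, len(d) - 1, loc=d.mean(),
                            scale=d.std(ddof=1) / np.sqrt(len(d)))
        row = out.iloc[0]
        assert row.p_adj == pytest.approx(p, rel=1e-12)
        assert row.ci_low == pytest.approx(ci[0], rel=1e-9)
        assert row.ci_high == pytest.approx(ci[1], rel=1e-9)
        assert row.ci_low <= row.mean_diff <= row.ci_high

    def test_identical_conditions_ci_spans_zero(self, rng):
        vals = rng.normal(size=10)
        df = pd.DataFrame([{"worker_id": i, "cond": c, "value": vals[i]}
                           for i in range(10) for c in ("a", "b")])
        row = stats.bonferroni_posthoc(df, within="cond").iloc[0]
        assert row.mean_diff == 0.0
        assert row.ci_low <= 0.0 <= row.ci_high

    def test_adjustment_is_m_times_p_capped(self, rng):
        df = long_table(rng, 12, ["a", "b", "c"], effect=0.3)
        out = stats.bonferroni_posthoc(df, within="cond")
        assert len(out) == 3
        for _, row in out.iterrows():
            assert row.p_adj == pytest.approx(min(1.0, 3 * row.p_unc), rel=1e-12)

    def test_empty_pairs_rejected(self, rng):
        df = long_table(rng, 5, ["a", "b"])
        with pytest.raises(ValidationError):
            stats.bonferroni_posthoc(df, within="cond", pairs=[])


@pytest.mark.parametrize("value,label", [
    (0.55, "large"), (0.14, "large"), (0.06, "medium"),
    (0.01, "small"), (0.005, "negligible"),
])
def test_effect_size_labels(value, label):
    assert stats.effect_size_label(value) == label
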