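"""Statistics layer: ANOVA, Tukey HSD, Pearson, Kaplan-Meier/Gehan, box plots."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neuroaging import stats as ns


def gehan_chi2_oracle(time, group, event):
    """Gehan-Breslow chi-square from first principles (risk-table loops).

    Weighted log-rank with w_i = n_i (number at risk), the weighting that
    emphasizes early events; score vector and hypergeometric covariance
    accumulated event time by event time, chi2 = U' V^-1 U over k-1 groups.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    names = sorted(set(group))
    g = np.array([names.index(x) for x in group])
    k = len(names)
    U = np.zeros(k)
    V = np.zeros((k, k))
    for t in sorted(set(time[event])):
        at_risk = time >= t
        n = at_risk.sum()
        d = (event & (time == t)).sum()
        ng = np.array([(at_risk & (g == j)).sum() for j in range(k)])
        dg = np.array([(event & (time == t) & (g == j)).sum() for j in range(k)])
        U += n * (dg - d * ng / n)
        if n > 1:
            c = n**2 * d * (n - d) / (n - 1)
            for a in range(k):
                for b in range(k):
                    V[a, b] += c * (ng[a] / n) * ((a == b) - ng[b] / n)
    return float(U[:-1] @ np.linalg.solve(V[:-1, :-1], U[:-1]))


def mixed_table(rng, n_per_group=17, n_groups=3, n_levels=5, shift=None):
    rows = []
    for gi in range(n_groups):
        for si in range(n_per_group):
            subj = f"g{gi}s{si}"
            base = rng.normal()  # subject random effect
            for li in range(n_levels):
                y = base + rng.normal()
                if shift is not None:
                    y += shift[gi]
                rows.append((f"grp{gi}", subj, f"lev{li}", y))
    return pd.DataFrame(rows, columns=["age", "animal", "level", "y"])


class TestMixedAnova:
    def test_identical_groups_give_f_near_zero(self):
        df = mixed_table(np.random.default_rng(0), n_per_group=10)
        # make the two halves literally identical responses
        wide = df[df["age"] == "grp0"].copy()
        clone = wide.copy()
        clone["age"] = "grp1"
        clone["animal"] = clone["animal"] + "c"
        table = pd.concat([wide, clone])
        res, dropped = ns.mixed_anova(table, "y", "age", "level")
        between = next(r for r in res if r.source == "age")
        assert between.F == pytest.approx(0.0, abs=1e-10)
        assert between.p == pytest.approx(1.0)
        assert dropped == 0

    def test_single_within_level_reduces_to_oneway_between(self):
        rng = np.random.default_rng(1)
        df = mixed_table(rng, n_per_group=12, n_levels=1)
        res, _ = ns.mixed_anova(df, "y", "age", within=None)
        groups = [g["y"].to_numpy() for _, g in df.groupby("age")]
        f_ref, p_ref = sps.f_oneway(*groups)
        assert res[0].F == pytest.approx(f_ref)
        assert res[0].p == pytest.approx(p_ref)
        assert res[0].df_num == 2 and res[0].df_den == 33

    def test_incomplete_subjects_dropped_listwise(self):
        df = mixed_table(np.random.default_rng(2), n_per_group=8)
        df = df[~((df["animal"] == "g0s0") & (df["level"] == "lev3"))]
        res, dropped = ns.mixed_anova(df, "y", "age", "level")
        assert dropped == 1
        between = next(r for r in res if r.source == "age")
        assert between.df_den == 23 - 3  # 23 retained animals, 3 groups

    def test_known_shift_detected(self):
        df = mixed_table(np.random.default_rng(3), shift=[0.0, 0.0, 2.0])
        res, _ = ns.mixed_anova(df, "y", "age", "level")
        between = next(r for r in res if r.source == "age")
        assert between.p < 0.001

    def test_single_between_level_rejected(self):
        df = mixed_table(np.random.default_rng(4))
        with pytest.raises(ValueError):
            ns.mixed_anova(df[df["age"] == "grp0"], "y", "age", "level")


class TestTukey:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=12)
        df = pd.DataFrame({"g": ["a"] * 12 + ["b"] * 12 + ["c"] * 12,
                           "y": np.concatenate([y, y, y])})
        out = ns.tukey_hsd(df, "y", "g")
        assert (out["p_tukey"] > 0.999).all()

    def test_two_groups_match_studentized_range_of_t(self):
        # with k=2 the Tukey q equals sqrt(2)|t|; p = P(Q_{2,df} > q)
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 12)
        df = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 12, "y": np.concatenate([a, b])})
        p_tukey = ns.tukey_hsd(df, "y", "g")["p_tukey"].iloc[0]
        t, _ = sps.ttest_ind(a, b)
        q = math.sqrt(2.0) * abs(t)
        p_oracle = sps.studentized_range.sf(q, 2, 20)
        assert p_tukey == pytest.approx(p_oracle, rel=1e-6)

    def test_extreme_pair_has_smallest_p(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({
            "g": ["lo"] * 15 + ["mid"] * 15 + ["hi"] * 15,
            "y": np.concatenate([rng.normal(0, 1, 15), rng.normal(1, 1, 15),
                                 rng.normal(2, 1, 15)]),
        })
        out = ns.tukey_hsd(df, "y", "g").set_index(["group_a", "group_b"])
        assert out.loc[("hi", "lo"), "p_tukey"] == out["p_tukey"].min()

    def test_tukey_p_at_least_unadjusted_p(self):
        # unadjusted comparison with the same pooled error term (t with
        # MSE over all groups, df = N - k)
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "g": np.repeat(["a", "b", "c", "d"], 9),
            "y": rng.normal(size=36) + np.repeat([0.0, 0.3, 0.6, 1.0], 9),
        })
        out = ns.tukey_hsd(df, "y", "g")
        groups = {k: v["y"].to_numpy() for k, v in df.groupby("g")}
        n_tot, k = len(df), len(groups)
        mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / (n_tot - k)
        for row in out.itertuples():
            a, b = groups[row.group_a], groups[row.group_b]
            se = math.sqrt(mse * (1 / len(a) + 1 / len(b)))
            t = abs(a.mean() - b.mean()) / se
            p_unadj = 2.0 * sps.t.sf(t, n_tot - k)
            assert row.p_tukey >= p_unadj - 1e-12


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, r2, p = ns.pearson(x, 3.0 * x + 1.0)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_sign_flip_negates_r_preserves_r2(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=16), rng.normal(size=16)
        r1, r2_1, p1 = ns.pearson(x, y)
        r2, r2_2, p2 = ns.pearson(x, -y)
        assert r2 == pytest.approx(-r1)
        assert r2_2 == pytest.approx(r2_1)
        assert p2 == pytest.approx(p1)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(10)
        ps = [ns.pearson(rng.normal(size=16), rng.normal(size=16))[2] for _ in range(1000)]
        # KS against U(0,1)
        d, p = sps.kstest(ps, "uniform")
        assert p > 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ns.pearson([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            ns.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def survival_records(times, events, groups):
    return [ns.SurvivalRecord(f"m{i}", g, t, bool(e))
            for i, (t, e, g) in enumerate(zip(times, events, groups))]


class TestKMWilcoxon:
    def test_no_events_curves_at_one_chi2_zero(self):
        recs = survival_records([75.0] * 20, [False] * 20, ["y"] * 10 + ["a"] * 10)
        curves, chi2, p = ns.km_wilcoxon(recs)
        assert chi2 == 0.0 and p == 1.0
        for c in curves.values():
            assert (c["survival"] == 1.0).all()

    def test_two_group_fixed_events_match_brute_force(self):
        # 17 vs 17; six deaths at fixed times in one group, none in the other
        times = [20.0, 30.0, 40.0, 50.0, 60.0, 70.0] + [75.0] * 11 + [75.0] * 17
        events = [True] * 6 + [False] * 28
        groups = ["aged"] * 17 + ["young"] * 17
        _, chi2, _ = ns.km_wilcoxon(survival_records(times, events, groups))
        oracle = gehan_chi2_oracle(times, groups, events)
        assert chi2 == pytest.approx(oracle, rel=1e-9)

    def test_three_group_51_animals_match_brute_force(self, rng):
        times = np.concatenate([rng.uniform(20, 74, 17).round(1),
                                np.full(17, 75.0), np.full(17, 75.0)])
        events = np.concatenate([rng.random(17) < 0.5, np.zeros(34, bool)])
        groups = ["aged"] * 17 + ["middle"] * 17 + ["young"] * 17
        _, chi2, _ = ns.km_wilcoxon(survival_records(times, events, groups))
        oracle = gehan_chi2_oracle(times, groups, events)
        assert chi2 == pytest.approx(oracle, rel=1e-9)

    def test_invariant_under_monotone_time_transform(self, rng):
        times = np.concatenate([rng.uniform(10, 70, 15), np.full(15, 75.0)])
        events = np.concatenate([rng.random(15) < 0.6, np.zeros(15, bool)])
        groups = ["a"] * 15 + ["y"] * 15
        _, chi2_1, _ = ns.km_wilcoxon(survival_records(times, events, groups))
        _, chi2_2, _ = ns.km_wilcoxon(survival_records(2.0 * times, events, groups))
        _, chi2_3, _ = ns.km_wilcoxon(survival_records(np.sqrt(times), events, groups))
        assert chi2_2 == pytest.approx(chi2_1, rel=1e-9)
        assert chi2_3 == pytest.approx(chi2_1, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            ns.km_wilcoxon(survival_records([10.0, 20.0], [True, True], ["a", "a"]))


class TestBoxplot:
    def test_constant_data_degenerate_box(self):
        s = ns.boxplot_summary([3.0] * 10)
        assert s.median == s.q25 == s.q75 == s.whisker_low == s.whisker_high == 3.0
        assert s.outliers == ()

    def test_1_to_100_has_no_outliers(self):
        s = ns.boxplot_summary(np.arange(1.0, 101.0))
        assert s.outliers == ()
        assert s.whisker_low == 1.0 and s.whisker_high == 100.0

    def test_point_beyond_fence_is_outlier(self):
        base = np.arange(1.0, 21.0)
        q25, q75 = np.percentile(base, [25, 75])
        extreme = q75 + 2.0 * (q75 - q25)
        s = ns.boxplot_summary(np.append(base, extreme))
        assert extreme in s.outliers

    def test_whiskers_are_outermost_inliers(self, rng):
        v = rng.normal(size=200)
        s = ns.boxplot_summary(v)
        iqr = s.q75 - s.q25
        assert s.whisker_low >= s.q25 - 1.5 * iqr
        assert s.whisker_high <= s.q75 + 1.5 * iqr
        assert s.whisker_low in v and s.whisker_high in v
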