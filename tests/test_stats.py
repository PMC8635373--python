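import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from scfc.matrices import ConnectivityMatrix
from scfc.stats import (
    ancova_group_test,
    behavior_coupling_analysis,
    edgewise_group_contrast,
    independent_corr_diff_test,
    pairwise_posthoc,
    pearson_corr_test,
)

from _oracles import partial_f_oracle


def _sse_full(y, group, age, sex):
    levels = list(pd.unique(group))
    dummies = np.column_stack([(group == g).astype(float) for g in levels[1:]])
    x = np.hstack([np.ones((len(y), 1)), dummies, age[:, None], sex[:, None]])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


def three_groups(rng, n=30, effect=(0.0, 0.0, 0.0)):
    group = np.repeat(["TDC", "ADHD-I", "ADHD-C"], n)
    age = rng.uniform(6, 17, 3 * n)
    sex = rng.integers(0, 2, 3 * n).astype(float)
    y = rng.normal(0, 1, 3 * n) + np.repeat(effect, n)
    return y, group, age, sex


class TestAncova:
    def test_matches_partial_f_oracle(self, rng):
        for _ in range(25):
            y, group, age, sex = three_groups(rng, n=int(rng.integers(5, 20)))
            res = ancova_group_test(y, group, age, sex)
            levels = list(pd.unique(group))
            dummies = np.column_stack([(group == g).astype(float) for g in levels[1:]])
            ones = np.ones((len(y), 1))
            x_full = np.hstack([ones, dummies, age[:, None], sex[:, None]])
            x_red = np.hstack([ones, age[:, None], sex[:, None]])
            f_exp, p_exp = partial_f_oracle(y, x_full, x_red)
            assert res.statistic == pytest.approx(f_exp, abs=1e-8)
            assert res.p == pytest.approx(p_exp, abs=1e-8)

    def test_matches_pingouin_ancova(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y, group, age, sex = three_groups(rng, n=25, effect=(0.0, 0.4, 0.8))
        res = ancova_group_test(y, group, age, sex)
        df = pd.DataFrame({"y": y, "group": group, "age": age, "sex": sex})
        aov = pingouin.ancova(data=df, dv="y", between="group", covar=["age", "sex"])
        row = aov.set_index("Source").loc["group"]
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        assert res.statistic == pytest.approx(row["F"], rel=1e-6)
        assert res.p == pytest.approx(row[p_col], rel=1e-6)

    def test_group_sum_of_squares_matches_anova_when_covariates_orthogonal(self, rng):
        # with covariates orthogonalized against the group dummies the sum
        # of squares attributed to group equals the plain one-way ANOVA
        # between-group SS, so the partial-F numerator reduces to the ANOVA
        # contrast
        n = 24
        group = np.repeat(["TDC", "ADHD-I", "ADHD-C"], n)
        dummies = np.column_stack(
            [(group == g).astype(float) for g in ("TDC", "ADHD-I", "ADHD-C")]
        )

        def orthogonalize(v):
            return v - dummies @ np.linalg.lstsq(dummies, v, rcond=None)[0] + v.mean()

        age = orthogonalize(rng.uniform(6, 17, 3 * n))
        sex = orthogonalize((np.arange(3 * n) % 2).astype(float))
        y = rng.normal(0, 1, 3 * n) + np.repeat([0.0, 0.5, 1.0], n) + 0.05 * age
        res = ancova_group_test(y, group, age, sex)
        ss_group_ancova = res.statistic * res.df[0] * (
            _sse_full(y, group, age, sex) / res.df[1]
        )
        grand = y.mean()
        ss_between = sum(
            (group == g).sum() * (y[group == g].mean() - grand) ** 2
            for g in ("TDC", "ADHD-I", "ADHD-C")
        )
        assert ss_group_ancova == pytest.approx(ss_between, rel=1e-8)

    def test_constant_response_gives_zero_f(self):
        group = np.repeat(["TDC", "ADHD-I", "ADHD-C"], 5)
        res = ancova_group_test(
            np.ones(15), group, np.linspace(6, 17, 15), np.tile([0, 1, 0, 1, 0], 3)
        )
        assert res.statistic == 0.0

    def test_group_means_and_sems_reported(self, rng):
        y, group, age, sex = three_groups(rng, n=10, effect=(0.0, 1.0, 2.0))
        res = ancova_group_test(y, group, age, sex)
        for g in ("TDC", "ADHD-I", "ADHD-C"):
            vals = y[group == g]
            assert res.group_means[g] == pytest.approx(vals.mean())
            assert res.group_sems[g] == pytest.approx(sps.sem(vals))

    def test_too_few_groups_rejected(self, rng):
        with pytest.raises(ValueError, match="groups"):
            ancova_group_test(
                rng.normal(size=10), ["TDC"] * 10, rng.uniform(6, 17, 10), np.zeros(10)
            )


class TestPosthoc:
    def test_unknown_method_rejected(self, rng):
        y, group, *_ = three_groups(rng, n=5)
        with pytest.raises(ValueError, match="method"):
            pairwise_posthoc(y, group, method="scheffe")

    def test_bonferroni_arithmetic(self, rng):
        y, group, *_ = three_groups(rng, n=40, effect=(0.0, 0.5, 1.0))
        welch = pairwise_posthoc(y, group, method="welch_t")
        bonf = pairwise_posthoc(y, group, method="bonferroni")
        for w, b in zip(welch, bonf):
            assert b.adjusted_p == pytest.approx(min(1.0, w.p * 3))

    def test_welch_matches_scipy(self, rng):
        y, group, *_ = three_groups(rng, n=20, effect=(0.0, 0.3, 0.9))
        for res in pairwise_posthoc(y, group, method="welch_t"):
            g1, g2 = res.extra["pair"]
            ref = sps.ttest_ind(y[group == g1], y[group == g2], equal_var=False)
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue)

    def test_all_pairs_present(self, rng):
        y, group, age, sex = three_groups(rng, n=10)
        res = pairwise_posthoc(y, group, covariates=np.column_stack([age, sex]))
        assert len(res) == 3

    def test_tukey_dominates_pooled_t(self, rng):
        # Tukey-Kramer adjusted p is never smaller than the pooled-variance
        # pairwise t-test p on the same data
        for _ in range(30):
            y, group, *_ = three_groups(rng, n=int(rng.integers(8, 25)))
            for res in pairwise_posthoc(y, group, method="tukey"):
                g1, g2 = res.extra["pair"]
                ref = sps.ttest_ind(y[group == g1], y[group == g2], equal_var=True)
                assert res.adjusted_p >= ref.pvalue - 1e-12

    def test_identical_groups_rarely_significant(self, rng):
        # null: median adjusted p across replicates well above 0.05
        ps = []
        for _ in range(100):
            y, group, *_ = three_groups(rng, n=50)
            ps.extend(r.adjusted_p for r in pairwise_posthoc(y, group, method="tukey"))
        assert np.median(ps) > 0.5


class TestEdgewiseContrast:
    @staticmethod
    def matrices_from(rng, n_subj, n_nodes=8, shift_edge=None, shift=0.0):
        mats = []
        labels = [f"n{i}" for i in range(n_nodes)]
        for _ in range(n_subj):
            vals = rng.normal(0.3, 0.1, (n_nodes, n_nodes))
            if shift_edge is not None:
                vals[shift_edge] += shift
            vals = np.triu(vals, 1)
            vals += vals.T
            mats.append(ConnectivityMatrix(vals, labels, "FC"))
        return mats

    def test_identical_groups_empty_mask(self, rng):
        mats = self.matrices_from(rng, 12)
        res = edgewise_group_contrast(mats, [m for m in mats], q=0.05)
        assert not res["mask"].any()

    def test_shifted_edge_detected(self, rng):
        a = self.matrices_from(rng, 30, shift_edge=(1, 2), shift=0.5)  # 5 SD
        b = self.matrices_from(rng, 30)
        res = edgewise_group_contrast(a, b, q=0.05)
        assert res["mask"][1, 2]
        assert res["t_map"][1, 2] > 0

    def test_zero_variance_edges_excluded(self, rng):
        a = self.matrices_from(rng, 10)
        b = self.matrices_from(rng, 10)
        for m in a + b:
            m.values[0, 1] = m.values[1, 0] = 0.0
        res = edgewise_group_contrast(a, b, q=0.05)
        assert res["n_excluded"] == 1
        assert np.isnan(res["edges"]["t"].iloc[0])

    def test_log1p_transform_applied_to_counts(self, rng):
        labels = [f"n{i}" for i in range(4)]

        def sc_mats(mult):
            out = []
            for _ in range(10):
                vals = np.triu(rng.integers(1, 20, (4, 4)).astype(float) * mult, 1)
                vals += vals.T
                out.append(ConnectivityMatrix(vals, labels, "SC"))
            return out

        res = edgewise_group_contrast(
            sc_mats(1), sc_mats(50), edge_transform="log1p_sc", q=0.05
        )
        assert (res["t_map"][np.triu_indices(4, 1)] < 0).all()

    def test_too_few_subjects_rejected(self, rng):
        mats = self.matrices_from(rng, 3)
        with pytest.raises(ValueError, match="subjects"):
            edgewise_group_contrast(mats[:1], mats)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_corr_test(x, x).statistic == pytest.approx(1.0)
        assert pearson_corr_test(x, -x).statistic == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # cov = 2.5, var_x = 2.5, var_y = 3.7 -> r = 2.5/sqrt(9.25) = 0.82199
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 6.0])
        res = pearson_corr_test(x, y)
        assert res.statistic == pytest.approx(2.5 / np.sqrt(9.25), abs=1e-10)
        t = res.statistic * np.sqrt(3) / np.sqrt(1 - res.statistic**2)
        assert res.p == pytest.approx(2 * sps.t.sf(t, 3), abs=1e-12)
        assert res.df == (3.0,)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_corr_test(np.ones(5), np.arange(5.0))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            pearson_corr_test(np.arange(3.0), np.arange(3.0))


class TestIndependentCorrDiff:
    def test_equal_correlations_give_zero_z(self):
        res = independent_corr_diff_test(0.4, 50, 0.4, 80)
        assert res.z == 0.0 and res.p == pytest.approx(1.0)

    def test_published_worked_example(self):
        # r = 0.25 (n=75) vs r = 0.62 (n=70) -> p about 0.0057
        res = independent_corr_diff_test(0.25, 75, 0.62, 70)
        assert res.p == pytest.approx(0.0057, abs=2e-4)

    def test_antisymmetric_in_group_order(self):
        a = independent_corr_diff_test(0.25, 75, 0.62, 70)
        b = independent_corr_diff_test(0.62, 70, 0.25, 75)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    @pytest.mark.parametrize("r1,n1,r2,n2", [(1.0, 50, 0.2, 50), (0.5, 3, 0.2, 50)])
    def test_invalid_inputs_rejected(self, r1, n1, r2, n2):
        with pytest.raises(ValueError):
            independent_corr_diff_test(r1, n1, r2, n2)


class TestBehaviorCouplingAnalysis:
    @staticmethod
    def cohort_frame(rng, n=40, slope_adhd_i=0.0):
        groups = np.repeat(["TDC", "ADHD-I", "ADHD-C"], n)
        ids = [f"s{i}" for i in range(3 * n)]
        coupling = pd.Series(rng.normal(0.3, 0.1, 3 * n), index=ids)
        hyper = rng.normal(0, 1, 3 * n)
        hyper[groups == "ADHD-I"] += slope_adhd_i * (
            (coupling[groups == "ADHD-I"] - 0.3) / 0.1
        )
        manifest = pd.DataFrame(
            {"group": groups, "swan_hyper": hyper, "swan_inatt": rng.normal(0, 1, 3 * n)},
            index=ids,
        )
        return coupling, manifest

    def test_report_shape(self, rng):
        coupling, manifest = self.cohort_frame(rng)
        out = behavior_coupling_analysis(coupling, manifest)
        assert len(out["correlations"]) == 3 * 2  # groups x score types
        assert len(out["differences"]) == 3 * 2  # pairs x score types

    def test_negative_slope_recovered(self, rng):
        coupling, manifest = self.cohort_frame(rng, n=75, slope_adhd_i=-0.8)
        out = behavior_coupling_analysis(coupling, manifest)
        row = out["correlations"].query("score == 'swan_hyper' and group == 'ADHD-I'")
        assert row["r"].iloc[0] < 0 and row["p"].iloc[0] < 0.05

    def test_constant_scores_flagged_not_estimable(self, rng):
        coupling, manifest = self.cohort_frame(rng)
        manifest["swan_hyper"] = 1.0
        out = behavior_coupling_analysis(coupling, manifest)
        hyper_rows = out["correlations"].query("score == 'swan_hyper'")
        assert not hyper_rows["estimable"].any()

    def test_missing_scores_counted(self, rng):
        coupling, manifest = self.cohort_frame(rng)
        manifest.loc[manifest.index[:5], "swan_hyper"] = np.nan
        out = behavior_coupling_analysis(coupling, manifest)
        assert out["correlations"]["n_missing"].sum() == 5

    def test_spearman_estimator_available(self, rng):
        coupling, manifest = self.cohort_frame(rng)
        out = behavior_coupling_analysis(coupling, manifest, estimator="spearman")
        assert out["correlations"]["estimable"].all()
        with pytest.raises(ValueError, match="estimator"):
            behavior_coupling_analysis(coupling, manifest, estimator="kendall")
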