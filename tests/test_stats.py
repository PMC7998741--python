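"""Covariate screening, ANCOVA/EMMs, effect sizes, chi-square, power."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from pabcog import stats
from pabcog.stats import (
    adherence_test,
    ancova,
    anova_power,
    anova_power_n,
    association_suite,
    chi_square_independence,
    cohens_d_adjusted,
    cohens_d_raw,
    subset_sensitivity,
    vif_screen,
)


class TestVif:
    def test_independent_covariates_have_vif_near_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((10_000, 2)), columns=["a", "b"])
        vifs = vif_screen(df)
        assert all(abs(v - 1.0) < 0.05 for v in vifs.values())

    def test_near_collinear_pair_is_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1e-6 * rng.standard_normal(500)})
        vifs = vif_screen(df)
        assert stats.flag_high_vif(vifs) == ["x", "y"]

    def test_perfect_collinearity_reports_inf_not_exception(self):
        x = np.arange(50.0)
        vifs = vif_screen(pd.DataFrame({"x": x, "y": 2 * x}))
        assert np.isinf(vifs["x"]) and np.isinf(vifs["y"])

    def test_two_covariate_vif_matches_closed_form(self):
        # VIF = 1/(1-r^2) exactly in the two-covariate case
        rng = np.random.default_rng(2)
        z1, z2 = rng.standard_normal((2, 2000))
        fat = z1
        muscle = -0.9 * z1 + np.sqrt(1 - 0.81) * z2
        df = pd.DataFrame({"fat": fat, "muscle": muscle})
        r = np.corrcoef(fat, muscle)[0, 1]
        vifs = vif_screen(df)
        assert vifs["fat"] == pytest.approx(1 / (1 - r**2), rel=1e-9)
        assert vifs["muscle"] == pytest.approx(1 / (1 - r**2), rel=1e-9)


def simulate_groups(rng, means, n_per_group, sd=1.0, n_cov=0, cov_beta=0.0):
    groups, y, covs = [], [], []
    for g, (mu, n) in enumerate(zip(means, n_per_group)):
        z = rng.standard_normal((n, n_cov)) if n_cov else np.empty((n, 0))
        eps = rng.standard_normal(n) * sd
        y.append(mu + z.sum(axis=1) * cov_beta + eps)
        covs.append(z)
        groups += [f"G{g}"] * n
    return (
        np.concatenate(y),
        pd.Series(groups),
        pd.DataFrame(np.vstack(covs), columns=[f"c{i}" for i in range(n_cov)]),
    )


class TestAncova:
    def test_zero_variance_covariate_degenerates_to_anova(self):
        rng = np.random.default_rng(3)
        y, g, _ = simulate_groups(rng, [0, 0.5, 1.0], [20, 25, 30])
        const = pd.DataFrame({"c": np.ones(len(y))})
        res = ancova(y, g, const)
        F, p = sps.f_oneway(*[y[g.values == lv] for lv in ("G0", "G1", "G2")])
        assert res.F == pytest.approx(F, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-12)
        assert res.df_error == len(y) - 3

    def test_emms_equal_raw_means_without_covariate_effects(self):
        rng = np.random.default_rng(4)
        y, g, z = simulate_groups(rng, [0, 1.0], [200, 200], n_cov=2, cov_beta=0.0)
        res = ancova(y, g, z)
        for lv in ("G0", "G1"):
            raw = y[g.values == lv].mean()
            assert abs(res.emm[lv][0] - raw) < 0.05

    def test_df_arithmetic_matches_group_and_covariate_counts(self):
        rng = np.random.default_rng(5)
        y, g, z = simulate_groups(rng, [0, 1, 2, 3], [26, 24, 34, 19], n_cov=3)
        res = ancova(y, g, z)
        assert res.df_between == 3
        assert res.df_error == 103 - 4 - 3 == 96
        # the study's printed df arise from 99 complete cases
        y2, g2, z2 = y[:99], g[:99], z.iloc[:99]
        res2 = ancova(y2, g2, z2)
        assert res2.df_error == 99 - 4 - 3 == 92

    def test_missing_outcome_rows_are_dropped_listwise(self):
        rng = np.random.default_rng(6)
        y, g, z = simulate_groups(rng, [0, 1], [30, 30], n_cov=1)
        y[::10] = np.nan
        res = ancova(y, g, z)
        assert res.n_complete == 54 and res.n_dropped == 6

    def test_group_with_no_complete_cases_raises_naming_it(self):
        rng = np.random.default_rng(7)
        y, g, z = simulate_groups(rng, [0, 1], [20, 20], n_cov=1)
        y[g.values == "G1"] = np.nan
        with pytest.raises(ValueError, match="G1"):
            ancova(y, g, z)

    def test_size_weighted_emms_reproduce_the_grand_mean(self):
        rng = np.random.default_rng(8)
        y, g, z = simulate_groups(rng, [0, 1, 3], [15, 35, 20], n_cov=2, cov_beta=0.7)
        res = ancova(y, g, z)
        weighted = sum(res.emm[lv][0] * res.group_n[lv] for lv in res.emm) / res.n_complete
        assert weighted == pytest.approx(y.mean(), abs=1e-9)

    def test_bonferroni_never_below_raw_and_capped(self):
        rng = np.random.default_rng(9)
        y, g, z = simulate_groups(rng, [0, 0, 0, 0], [12, 12, 12, 12], n_cov=1)
        res = ancova(y, g, z)
        for pw in res.pairwise:
            assert pw.adjusted_p >= pw.raw_p
            assert pw.adjusted_p <= 1.0
            assert pw.ci95_low <= pw.cohens_d <= pw.ci95_high

    def test_null_type_one_error_is_calibrated(self):
        rng = np.random.default_rng(10)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            y, g, z = simulate_groups(rng, [0, 0, 0], [20, 20, 20], n_cov=2, cov_beta=0.5)
            if ancova(y, g, z).p < 0.05 :
                rejections += 1
        lo, hi = sps.binom.interval(0.95, n_rep, 0.05)
        assert lo <= rejections <= hi


class TestCohensD:
    def test_equal_means_give_zero_with_symmetric_ci(self):
        d, lo, hi = cohens_d_adjusted(5.0, 0.2, 30, 5.0, 0.25, 25)
        assert d == 0.0
        assert lo == pytest.approx(-hi)

    def test_study_scale_emm_inputs_reproduce_printed_effect_size(self):
        # Sports vs Admin SB-ratio comparison from printed EMMs/SEs/ns
        d, lo, hi = cohens_d_adjusted(0.587, 0.020, 34, 0.468, 0.022, 24)
        assert d == pytest.approx(1.06, abs=0.02)
        assert lo == pytest.approx(0.51, abs=0.03)
        assert hi == pytest.approx(1.61, abs=0.03)

    def test_formula_path_matches_raw_data_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.normal(2.0, 1.0, 40)
        b = rng.normal(1.2, 1.4, 25)
        d, lo, hi = cohens_d_raw(a, b)
        # independent arithmetic straight from the defining formulas
        sp = np.sqrt(((40 - 1) * a.var(ddof=1) + (25 - 1) * b.var(ddof=1)) / 63)
        d0 = (a.mean() - b.mean()) / sp
        se0 = np.sqrt(65 / 1000 + d0**2 / (2 * 63))
        assert d == pytest.approx(d0, abs=1e-9)
        assert lo == pytest.approx(d0 - 1.959963984540054 * se0, abs=1e-9)
        assert hi == pytest.approx(d0 + 1.959963984540054 * se0, abs=1e-9)

    def test_zero_pooled_sd_is_missing(self):
        d, lo, hi = cohens_d_adjusted(1.0, 0.0, 10, 2.0, 0.0, 10)
        assert np.isnan(d) and np.isnan(lo) and np.isnan(hi)


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        chi2, df, p = chi_square_independence([[10, 30], [20, 60], [5, 15]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_random_tables_match_direct_formula(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            obs = rng.integers(1, 60, size=(2, 4)).astype(float)
            chi2, df, p = chi_square_independence(obs)
            e = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            assert chi2 == pytest.approx(((obs - e) ** 2 / e).sum(), abs=1e-9)
            assert df == 3

    def test_invariant_under_row_and_column_permutation(self):
        obs = np.array([[2, 1, 10, 2], [24, 23, 24, 17]], dtype=float)
        chi2, *_ = chi_square_independence(obs)
        chi2_p, *_ = chi_square_independence(obs[::-1, ::-1])
        assert chi2 == pytest.approx(chi2_p, abs=1e-12)

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [5, 3]])

    def test_adherence_posthoc_flags_the_outlying_group(self):
        adh = adherence_test(
            {"H": 2, "A": 1, "S": 10, "N": 2}, {"H": 26, "A": 24, "S": 34, "N": 19}
        )
        ph = adh.posthoc.set_index("group")
        assert ph["adjusted_p"].idxmin() == "S"
        assert ph.loc["S", "adjusted_p"] < 0.05


class TestAssociations:
    def test_perfect_linear_relation_gives_unit_correlations(self):
        ids = [f"P{i}" for i in range(20)]
        x = np.linspace(0, 1, 20)
        pab = pd.DataFrame({"participant_id": ids, "sitting": x, "standing": x, "stepping": x})
        scores = pd.DataFrame(
            {"participant_id": ids, "inhibition": x, "shifting": x, "updating": x}
        )
        res = association_suite(pab, scores)
        c = res["correlations"]
        for m in ("pearson_r", "spearman_r", "kendall_r"):
            np.testing.assert_allclose(c[m].to_numpy(), 1.0)

    def test_kendall_tau_b_matches_pair_enumeration(self):
        rng = np.random.default_rng(13)
        x = rng.integers(0, 5, 30).astype(float)  # ties on purpose
        y = rng.integers(0, 5, 30).astype(float)
        conc = disc = tx = ty = 0
        for i in range(30):
            for j in range(i + 1, 30):
                dx, dy = x[i] - x[j], y[i] - y[j]
                if dx == 0 and dy == 0:
                    continue
                if dx == 0:
                    tx += 1
                elif dy == 0:
                    ty += 1
                elif dx * dy > 0:
                    conc += 1
                else:
                    disc += 1
        denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
        tau_oracle = (conc - disc) / denom
        tau, _ = sps.kendalltau(x, y)
        assert tau == pytest.approx(tau_oracle, abs=1e-12)

    def test_constant_variable_reports_missing_correlation(self):
        ids = [f"P{i}" for i in range(15)]
        pab = pd.DataFrame(
            {"participant_id": ids, "sitting": 5.0, "standing": np.arange(15.0),
             "stepping": np.arange(15.0)}
        )
        scores = pd.DataFrame(
            {"participant_id": ids, "inhibition": np.arange(15.0),
             "shifting": np.arange(15.0), "updating": np.arange(15.0)}
        )
        c = association_suite(pab, scores)["correlations"]
        cell = c[(c["pab_var"] == "sitting")]
        assert cell["pearson_r"].isna().all()

    def test_pairwise_complete_ns_are_reported_per_cell(self):
        ids = [f"P{i}" for i in range(30)]
        rng = np.random.default_rng(14)
        pab = pd.DataFrame(
            {"participant_id": ids, "sitting": rng.normal(size=30),
             "standing": rng.normal(size=30), "stepping": rng.normal(size=30)}
        )
        scores = pd.DataFrame(
            {"participant_id": ids, "inhibition": rng.normal(size=30),
             "shifting": rng.normal(size=30), "updating": rng.normal(size=30)}
        )
        scores.loc[:9, "updating"] = np.nan
        c = association_suite(pab, scores).get("correlations")
        assert (c.loc[c["cog_var"] == "updating", "n"] == 20).all()
        assert (c.loc[c["cog_var"] == "inhibition", "n"] == 30).all()


class TestSubsets:
    @staticmethod
    def _tables(n=40, seed=15):
        rng = np.random.default_rng(seed)
        ids = [f"P{i}" for i in range(n)]
        pab = pd.DataFrame(
            {"participant_id": ids, "sitting": rng.normal(size=n),
             "standing": rng.normal(size=n), "stepping": rng.normal(size=n)}
        )
        scores = pd.DataFrame(
            {"participant_id": ids, "inhibition": rng.normal(size=n),
             "shifting": rng.normal(size=n), "updating": rng.normal(size=n)}
        )
        return ids, pab, scores

    def test_empty_flag_reproduces_full_result(self):
        ids, pab, scores = self._tables()
        flags = pd.DataFrame({"participant_id": ids, "medication": False})
        out = subset_sensitivity(pab, scores, flags)
        sub = out["subsets"]["medication"]
        assert not sub["skipped"]
        pd.testing.assert_frame_equal(
            sub["result"]["correlations"], out["full"]["correlations"]
        )
        assert sub["conclusions_unchanged"]

    def test_tiny_subset_is_skipped_with_warning(self):
        ids, pab, scores = self._tables()
        flags = pd.DataFrame({"participant_id": ids, "age": [False] + [True] * 39})
        with pytest.warns(UserWarning, match="skipped"):
            out = subset_sensitivity(pab, scores, flags)
        assert out["subsets"]["age"]["skipped"]


class TestPower:
    def test_balanced_four_group_search_returns_the_study_n(self):
        assert anova_power_n(4, 0.40, 0.05, 0.80) == 76

    def test_unconstrained_search_is_smaller(self):
        n = anova_power_n(4, 0.40, 0.05, 0.80, equal_groups=False)
        assert n == 73
        assert anova_power(n, 4, 0.40) >= 0.80 > anova_power(n - 1, 4, 0.40)

    def test_vanishing_power_target_hits_minimal_feasible_n(self):
        assert anova_power_n(4, 0.40, 0.05, 0.051, equal_groups=False) == 5

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            anova_power_n(1, 0.4)
        with pytest.raises(ValueError):
            anova_power_n(4, -0.1)
        with pytest.raises(ValueError):
            anova_power_n(4, 0.4, alpha=0.9, power=0.8)

    def test_two_group_power_matches_simulation(self):
        # k=2: the omnibus F equals a two-sample t^2; simulate at the
        # returned N and compare the rejection rate with the nominal power
        k, f, alpha, target = 2, 0.4, 0.05, 0.80
        n_total = anova_power_n(k, f, alpha, target)
        predicted = anova_power(n_total, k, f, alpha)
        n = n_total // 2
        delta = 2 * f  # mean separation giving Cohen's f with two groups
        rng = np.random.default_rng(16)
        reps = 100_000
        a = rng.standard_normal((reps, n))
        b = rng.standard_normal((reps, n)) + delta
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        sp = np.sqrt((va + vb) / 2)
        t = (b.mean(axis=1) - a.mean(axis=1)) / (sp * np.sqrt(2 / n))
        crit = sps.t.isf(alpha / 2, 2 * n - 2)
        rate = float((np.abs(t) > crit).mean())
        assert rate == pytest.approx(predicted, abs=0.01)
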