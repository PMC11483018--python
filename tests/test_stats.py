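import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.formula.api as smf

from ppdwear import (
    StatsError,
    adjusted_mean,
    compare_cohorts,
    estimated_marginal_means,
    fit_lmm_random_intercept,
    fit_ols,
    pearson,
)

RACES = ["White non-Hispanic", "Another race or ethnicity"]


def simulate_cohort_data(rng, n=80, effect=0.0):
    cohort = np.where(rng.random(n) < 0.4, "PPD", "non_PPD")
    age = rng.normal(33, 4, n)
    race = rng.choice(RACES, n, p=[0.8, 0.2])
    y = (
        60.0
        + effect * (cohort == "PPD")
        + 0.3 * (age - 33)
        + 2.0 * (race == RACES[1])
        + rng.normal(0, 10, n)
    )
    return pd.DataFrame({"y": y, "cohort": cohort, "age": age, "race": race})


class TestFitOls:
    def test_cohort_only_model_recovers_group_means(self):
        rng = np.random.default_rng(0)
        d = simulate_cohort_data(rng, effect=5.0)
        fit = fit_ols(d.y, cohort=d.cohort)
        emms = {e.level: e.emm for e in estimated_marginal_means(fit)}
        for level, grp in d.groupby("cohort"):
            assert emms[level] == pytest.approx(grp.y.mean(), abs=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = simulate_cohort_data(rng, n=int(rng.integers(20, 50)))
        fit = fit_ols(d.y, cohort=d.cohort, age=d.age, race=d.race)
        # independent oracle: pseudo-inverse of the normal equations on a
        # hand-built design matrix
        X = np.column_stack(
            [
                np.ones(len(d)),
                (d.cohort == "PPD").to_numpy(float),
                (d.race == RACES[1]).to_numpy(float),
                d.age.to_numpy(),
            ]
        )
        beta = np.linalg.pinv(X.T @ X) @ X.T @ d.y.to_numpy()
        # columns: intercept, cohort[PPD], race[other], age
        np.testing.assert_allclose(fit.params, beta, atol=1e-10)

    def test_matches_statsmodels_covariance(self):
        rng = np.random.default_rng(9)
        d = simulate_cohort_data(rng)
        fit = fit_ols(d.y, cohort=d.cohort, age=d.age, race=d.race)
        sm_fit = smf.ols(
            "y ~ C(cohort, Treatment('non_PPD')) "
            "+ C(race, Treatment('White non-Hispanic')) + age",
            data=d,
        ).fit()
        np.testing.assert_allclose(
            sorted(fit.params), sorted(sm_fit.params), atol=1e-8
        )
        np.testing.assert_allclose(
            sorted(np.diag(fit.cov_params)),
            sorted(np.diag(sm_fit.cov_params())),
            atol=1e-8,
        )
        assert fit.df_resid == sm_fit.df_resid

    def test_constant_response(self):
        rng = np.random.default_rng(2)
        d = simulate_cohort_data(rng)
        fit = fit_ols(np.full(len(d), 7.0), cohort=d.cohort, age=d.age)
        assert fit.params[0] == pytest.approx(7.0)
        np.testing.assert_allclose(fit.params[1:], 0.0, atol=1e-10)
        assert fit.resid_var == pytest.approx(0.0, abs=1e-18)

    def test_rank_deficient_design_names_columns(self):
        n = 30
        rng = np.random.default_rng(3)
        age = rng.normal(33, 4, n)
        cohort = ["PPD"] * 15 + ["non_PPD"] * 15
        race = ["a"] * 15 + ["b"] * 15  # aliases the cohort factor
        with pytest.raises(StatsError, match="collinear"):
            fit_ols(rng.normal(size=n), cohort=cohort, age=age, race=race)


class TestEstimatedMarginalMeans:
    def test_no_covariate_model_equals_raw_means(self):
        rng = np.random.default_rng(4)
        d = simulate_cohort_data(rng)
        fit = fit_ols(d.y, cohort=d.cohort)
        for e in estimated_marginal_means(fit):
            assert e.emm == pytest.approx(
                d.loc[d.cohort == e.level, "y"].mean(), abs=1e-10
            )

    def test_balanced_centered_design_difference_is_coefficient(self):
        rng = np.random.default_rng(5)
        n = 40
        cohort = np.array(["PPD", "non_PPD"] * (n // 2))
        age = rng.normal(0, 4, n)
        age = age - age.mean()  # centered covariate
        y = 50 + 4.0 * (cohort == "PPD") + 0.5 * age + rng.normal(0, 3, n)
        fit = fit_ols(y, cohort=cohort, age=age)
        emms = {e.level: e.emm for e in estimated_marginal_means(fit)}
        j = list(fit.design.columns).index("cohort[PPD]")
        assert emms["PPD"] - emms["non_PPD"] == pytest.approx(
            fit.params[j], abs=1e-10
        )

    def test_equal_weight_emm_is_grid_enumeration_average(self):
        # brute-force oracle: average statsmodels predictions over every
        # factor combination of the reference grid
        rng = np.random.default_rng(6)
        d = simulate_cohort_data(rng)
        d["race"] = rng.choice(["a", "b", "c"], len(d))
        fit = fit_ols(d.y, cohort=d.cohort, age=d.age, race=d.race)
        sm_fit = smf.ols("y ~ C(cohort) + C(race) + age", data=d).fit()
        for e in estimated_marginal_means(fit, "cohort"):
            grid = pd.DataFrame(
                [
                    {"cohort": e.level, "race": r, "age": d.age.mean()}
                    for r in ["a", "b", "c"]
                ]
            )
            oracle = sm_fit.predict(grid).mean()
            assert e.emm == pytest.approx(oracle, abs=1e-8)

    def test_contrast_p_matches_statsmodels_t_test(self):
        rng = np.random.default_rng(7)
        d = simulate_cohort_data(rng, effect=4.0)
        fit = fit_ols(d.y, cohort=d.cohort, age=d.age, race=d.race)
        p = estimated_marginal_means(fit)[0].contrast_p
        sm_fit = smf.ols(
            "y ~ C(cohort, Treatment('non_PPD')) + C(race) + age", data=d
        ).fit()
        key = [k for k in sm_fit.pvalues.index if "cohort" in k][0]
        assert p == pytest.approx(sm_fit.pvalues[key], abs=1e-10)

    def test_invariant_to_reference_level_choice(self):
        rng = np.random.default_rng(8)
        d = simulate_cohort_data(rng, effect=3.0)
        a = estimated_marginal_means(
            fit_ols(d.y, cohort=d.cohort, age=d.age, race=d.race,
                    references={"cohort": "non_PPD", "race": RACES[0]})
        )
        b = estimated_marginal_means(
            fit_ols(d.y, cohort=d.cohort, age=d.age, race=d.race,
                    references={"cohort": "PPD", "race": RACES[1]})
        )
        am = {e.level: (e.emm, e.se) for e in a}
        bm = {e.level: (e.emm, e.se) for e in b}
        for level in am:
            assert am[level][0] == pytest.approx(bm[level][0], abs=1e-9)
            assert am[level][1] == pytest.approx(bm[level][1], abs=1e-9)

    def test_se_shrinks_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(10)
        sizes = [100, 200, 400, 800, 1600]
        log_se = []
        for n in sizes:
            ses = []
            for _ in range(5):
                cohort = np.array(["PPD", "non_PPD"])[
                    rng.integers(0, 2, n)
                ]
                y = 10 + rng.normal(0, 5, n)
                fit = fit_ols(y, cohort=cohort)
                ses.append(estimated_marginal_means(fit)[0].se)
            log_se.append(np.log(np.mean(ses)))
        slope = np.polyfit(np.log(sizes), log_se, 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)


def simulate_lmm(rng, n_persons=60, n_days=8, effect=0.0,
                 sigma_b=1.5, sigma_w=2.0, mean=17.0):
    pids, cohorts, ages, races, ys = [], [], [], [], []
    for i in range(n_persons):
        cohort = "PPD" if i % 2 == 0 else "non_PPD"
        age = rng.normal(33, 4)
        race = RACES[int(rng.random() < 0.2)]
        b = rng.normal(0, sigma_b)
        for _ in range(n_days):
            pids.append(f"p{i}")
            cohorts.append(cohort)
            ages.append(age)
            races.append(race)
            ys.append(
                mean + effect * (cohort == "PPD") + b + rng.normal(0, sigma_w)
            )
    return pd.DataFrame(
        {"person_id": pids, "cohort": cohorts, "age": ages,
         "race": races, "y": ys}
    )


class TestMixedModel:
    def test_zero_between_variance_collapses_to_ols(self):
        rng = np.random.default_rng(12)
        d = simulate_lmm(rng, sigma_b=0.0)
        lmm = fit_lmm_random_intercept(
            d.y, d.person_id, cohort=d.cohort, age=d.age, race=d.race
        )
        ols = fit_ols(d.y, cohort=d.cohort, age=d.age, race=d.race)
        assert lmm.sigma2_between == pytest.approx(0.0, abs=0.5)
        np.testing.assert_allclose(lmm.params, ols.params, atol=2e-2)
        if lmm.lambda_ratio == 0.0:
            np.testing.assert_allclose(lmm.params, ols.params, atol=1e-6)

    def test_balanced_design_matches_anova_closed_form(self):
        # classical one-way REML: sigma_w^2 = MSW, sigma_b^2 = (MSB - MSW)/k
        rng = np.random.default_rng(13)
        m, k = 30, 6
        b = rng.normal(0, 2.0, m)
        y = np.concatenate(
            [10 + b[i] + rng.normal(0, 1.5, k) for i in range(m)]
        )
        pids = np.repeat([f"p{i}" for i in range(m)], k)
        fit = fit_lmm_random_intercept(y, pids)
        means = y.reshape(m, k).mean(axis=1)
        msb = k * np.sum((means - y.mean()) ** 2) / (m - 1)
        msw = np.sum((y.reshape(m, k) - means[:, None]) ** 2) / (m * (k - 1))
        assert fit.sigma2_within == pytest.approx(msw, rel=1e-6)
        assert fit.sigma2_between == pytest.approx((msb - msw) / k, rel=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        rng = np.random.default_rng(14)
        d = simulate_lmm(rng, n_persons=40, n_days=5, effect=1.0)
        # drop some rows so the design is unbalanced
        d = d.sample(frac=0.85, random_state=1).reset_index(drop=True)
        fit = fit_lmm_random_intercept(
            d.y, d.person_id, cohort=d.cohort, age=d.age, race=d.race
        )
        sm_fit = smf.mixedlm(
            "y ~ C(cohort, Treatment('non_PPD')) "
            "+ C(race, Treatment('White non-Hispanic')) + age",
            data=d,
            groups=d.person_id,
        ).fit(reml=True)
        np.testing.assert_allclose(
            sorted(fit.params), sorted(sm_fit.fe_params), rtol=1e-4, atol=1e-4
        )
        assert fit.sigma2_within == pytest.approx(sm_fit.scale, rel=1e-3)
        assert fit.sigma2_between == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-2
        )

    def test_reml_criterion_is_local_maximum(self):
        rng = np.random.default_rng(15)
        d = simulate_lmm(rng)
        fit = fit_lmm_random_intercept(
            d.y, d.person_id, cohort=d.cohort, age=d.age
        )
        lam = fit.lambda_ratio
        assert lam > 0
        # bracket the returned ratio: nearby ratios give no better fit
        for factor in (0.9, 1.1):
            forced = _reml_at(d, lam * factor)
            assert forced <= fit.reml_loglik + 1e-7

    def test_parameter_recovery_across_replicates(self):
        # simulated cohort effect on daily hours: estimate within 3 SE of
        # the truth in nearly all replicates
        rng = np.random.default_rng(16)
        delta = 0.8
        hits = 0
        reps = 100
        for _ in range(reps):
            d = simulate_lmm(rng, n_persons=40, n_days=6, effect=delta)
            fit = fit_lmm_random_intercept(
                d.y, d.person_id, cohort=d.cohort
            )
            j = list(fit.design.columns).index("cohort[PPD]")
            est = fit.params[j]
            se = np.sqrt(fit.cov_params[j, j])
            hits += abs(est - delta) <= 3 * se
        assert hits / reps >= 0.95

    def test_single_person_rejected(self):
        with pytest.raises(StatsError, match="2 persons"):
            fit_lmm_random_intercept([1.0, 2.0, 3.0], ["a", "a", "a"])


def _reml_at(d, lam):
    """REML log-likelihood at a forced variance ratio (independent path)."""
    from ppdwear.stats import build_design

    X, _ = build_design({"cohort": d.cohort}, {"age": d.age})
    y = d.y.to_numpy()
    codes, _u = pd.factorize(d.person_id)
    n, p = X.shape
    m = codes.max() + 1
    counts = np.bincount(codes).astype(float)
    V = np.eye(n)
    for i in range(m):
        idx = np.flatnonzero(codes == i)
        V[np.ix_(idx, idx)] += lam
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    beta = np.linalg.solve(A, X.T @ Vinv @ y)
    r = y - X @ beta
    rss = r @ Vinv @ r
    s2 = rss / (n - p)
    _, logdetV = np.linalg.slogdet(V)
    _, logdetA = np.linalg.slogdet(A)
    return -0.5 * (
        (n - p) * np.log(s2) + logdetV + logdetA + (n - p) * (np.log(2 * np.pi) + 1)
    )


class TestPearson:
    def test_identity_and_antisymmetry(self):
        x = np.arange(10.0)
        assert pearson(x, x).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_direct_formula_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        res = pearson(x, y)
        r_direct = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert res.r == pytest.approx(r_direct, abs=1e-12)
        sp = scipy.stats.pearsonr(x, y)
        assert res.r == pytest.approx(sp.statistic, abs=1e-12)
        assert res.p == pytest.approx(sp.pvalue, abs=1e-12)

    def test_nan_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, np.nan, 10.0])
        assert pearson(x, y).n == 3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatsError, match="3 complete pairs"):
            pearson([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(StatsError, match="zero variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCompareCohorts:
    def _summaries(self, rng, n=60, delta=0.0):
        cohort = np.array(["PPD"] * n + ["non_PPD"] * n)
        pct = np.clip(
            rng.normal(60 + delta * (cohort == "PPD"), 15), 0, 100
        )
        return pd.DataFrame(
            {
                "person_id": [f"p{i}" for i in range(2 * n)],
                "period": "ppd",
                "pct_worn": pct,
                "cohort": cohort,
                "age": rng.normal(33, 4, 2 * n),
                "race": rng.choice(RACES, 2 * n),
                "empty": False,
            }
        )

    def test_unadjusted_output_equals_raw_group_means(self):
        rng = np.random.default_rng(20)
        d = self._summaries(rng, delta=8.0)
        res = compare_cohorts(d, "pct_worn", "ppd", adjust=False)
        assert res.emm_ppd == pytest.approx(
            d.loc[d.cohort == "PPD", "pct_worn"].mean()
        )
        assert res.emm_nonppd == pytest.approx(
            d.loc[d.cohort == "non_PPD", "pct_worn"].mean()
        )
        assert res.n_ppd == res.n_nonppd == 60

    def test_missing_cohort_raises(self):
        rng = np.random.default_rng(21)
        d = self._summaries(rng)
        with pytest.raises(StatsError, match="PPD"):
            compare_cohorts(
                d[d.cohort == "PPD"], "pct_worn", "ppd"
            )

    def test_empty_flagged_rows_excluded(self):
        rng = np.random.default_rng(22)
        d = self._summaries(rng)
        d.loc[:9, "empty"] = True
        res = compare_cohorts(d, "pct_worn", "ppd")
        assert res.n_ppd == 50


class TestAdjustedMean:
    def test_single_group_adjusted_mean_matches_emmeans_grid(self):
        rng = np.random.default_rng(23)
        n = 100
        age = rng.normal(33, 4, n)
        race = rng.choice(["a", "b", "c"], n)
        y = 50 + 0.4 * (age - 33) + 3 * (race == "b") + rng.normal(0, 5, n)
        fit = fit_ols(y, age=age, race=race)
        mean, se = adjusted_mean(fit)
        sm_fit = smf.ols(
            "y ~ C(race) + age",
            data=pd.DataFrame({"y": y, "age": age, "race": race}),
        ).fit()
        grid = pd.DataFrame(
            [{"race": r, "age": age.mean()} for r in ["a", "b", "c"]]
        )
        assert mean == pytest.approx(sm_fit.predict(grid).mean(), abs=1e-8)
        assert se > 0
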