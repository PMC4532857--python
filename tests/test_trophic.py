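"""Trophic statistics: NB GLMs, OLS links, rank tests, persistence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bogcascade import (categorize_persistence, deviance_explained,
                        fit_bird_glm, fit_bird_gam_check,
                        fit_moisture_regression, fit_negbin_glm,
                        kruskal_wallis, make_bird_counts,
                        make_cranefly_counts, pairwise_wilcoxon,
                        predict_cranefly, project_birds, sum_quartet,
                        year_correlation)
from bogcascade.trophic import REGIONS


def cranefly_dataset(n=2000, seed=0, intercept=5.203, slope=-0.333, theta=2.0):
    rng = np.random.default_rng(seed)
    wtd = rng.uniform(0, 15, n)
    regions = np.array(sorted(REGIONS), dtype=object)[np.arange(n) % 3]
    counts = make_cranefly_counts(wtd, regions, intercept=intercept,
                                  wtd_slope=slope, theta=theta, seed=seed + 1)
    return counts, pd.DataFrame({"wtd_cm": wtd, "region": regions})


class TestSumQuartet:
    def test_basic_sums(self):
        assert sum_quartet((0, 0, 0, 0)) == 0
        assert sum_quartet((3, 1, 0, 2)) == 6
        assert sum_quartet((2, 0, 3, 1)) == sum_quartet((1, 3, 0, 2))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sum_quartet((1, -1, 0, 0))


class TestNegbinGLM:
    def test_intercept_only_is_log_mean(self):
        fit = fit_negbin_glm([2, 4, 6], pd.DataFrame(index=range(3)))
        assert fit.params["(Intercept)"] == pytest.approx(np.log(4.0), abs=1e-6)

    def test_poisson_limit(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 2, 800)
        y = rng.poisson(np.exp(1.0 + 0.5 * x))
        fit = fit_negbin_glm(y, pd.DataFrame({"x": x}))
        assert fit.theta > 50  # effectively Poisson
        import statsmodels.api as sm

        X = sm.add_constant(x)
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fit.params["(Intercept)"] == pytest.approx(pois.params[0], abs=1e-3)
        assert fit.params["x"] == pytest.approx(pois.params[1], abs=1e-3)

    def test_recovers_printed_cranefly_model(self):
        counts, design = cranefly_dataset(n=5000, seed=3)
        fit = fit_negbin_glm(counts, design)
        se_i = fit.coef.loc["(Intercept)", "se"]
        se_s = fit.coef.loc["wtd_cm", "se"]
        assert abs(fit.params["(Intercept)"] - 5.203) < 4 * se_i
        assert abs(fit.params["wtd_cm"] - (-0.333)) < 4 * se_s
        assert fit.theta == pytest.approx(2.0, rel=0.15)
        assert fit.converged

    def test_agrees_with_joint_ml_oracle(self):
        """Alternating-profile fit matches statsmodels' joint NB ML fit."""
        counts, design = cranefly_dataset(n=800, seed=9)
        fit = fit_negbin_glm(counts, design)
        import statsmodels.api as sm
        from bogcascade.trophic import build_design

        X, _ = build_design(design)
        oracle = np.asarray(sm.NegativeBinomial(counts, X).fit(disp=0).params)
        for i, name in enumerate(X.columns):
            assert fit.params[name] == pytest.approx(oracle[i], abs=5e-3)
        assert fit.theta == pytest.approx(1.0 / oracle[-1], rel=0.02)

    def test_reference_level_is_alphabetical(self):
        counts, design = cranefly_dataset(n=600, seed=5)
        fit = fit_negbin_glm(counts, design)
        assert "region[MidWales]" not in fit.coef.index
        assert "region[NorthYorkMoors]" in fit.coef.index
        assert fit.factor_levels["region"][0] == "MidWales"

    def test_rank_deficient_design_rejected(self):
        y = [1, 2, 3, 4, 5, 6]
        design = pd.DataFrame({"a": [1, 2, 3, 4, 5, 6],
                               "b": [2, 4, 6, 8, 10, 12]})
        with pytest.raises(ValueError):
            fit_negbin_glm(y, design)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_negbin_glm([1.5, 2.0, 3.0], pd.DataFrame(index=range(3)))


class TestDevianceExplained:
    def test_arithmetic(self):
        counts, design = cranefly_dataset(n=400, seed=2)
        fit = fit_negbin_glm(counts, design)
        frac = deviance_explained(fit)
        assert 0.0 <= frac <= 1.0
        assert frac == pytest.approx(
            (fit.null_deviance - fit.residual_deviance) / fit.null_deviance)

    def test_residual_never_exceeds_null(self):
        counts, design = cranefly_dataset(n=400, seed=12)
        fit = fit_negbin_glm(counts, design)
        assert fit.residual_deviance <= fit.null_deviance + 1e-8


class TestPredictCranefly:
    def _fit(self):
        counts, design = cranefly_dataset(n=1500, seed=4)
        return fit_negbin_glm(counts, design)

    def test_monotone_decreasing_in_wtd(self):
        fit = self._fit()
        w = np.linspace(0, 20, 50)
        pred = predict_cranefly(w, fit)
        assert np.all(np.diff(pred) < 0)
        assert np.all(pred > 0)

    def test_matches_linear_predictor_brute_force(self):
        fit = self._fit()
        rng = np.random.default_rng(0)
        for _ in range(100):
            w = rng.uniform(0, 25)
            region = rng.choice(sorted(REGIONS))
            eta = fit.params["(Intercept)"] + fit.params["wtd_cm"] * w
            key = f"region[{region}]"
            if key in fit.params.index:
                eta += fit.params[key]
            assert predict_cranefly(w, fit, region) == pytest.approx(np.exp(eta))

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            predict_cranefly(5.0, self._fit(), "Atlantis")


class TestMoistureRegression:
    def test_exact_line(self):
        w = np.linspace(0, 30, 20)
        m = 1.013 - 0.031 * w
        fit = fit_moisture_regression(m, w)
        assert fit.intercept == pytest.approx(1.013)
        assert fit.slope == pytest.approx(-0.031)
        assert fit.r_squared == pytest.approx(1.0)

    def test_recovers_printed_relationship(self):
        rng = np.random.default_rng(6)
        w = rng.uniform(0, 30, 2000)
        m = 1.013 - 0.031 * w + rng.normal(0, 0.3, 2000)
        fit = fit_moisture_regression(m, w)
        assert fit.intercept == pytest.approx(1.013, abs=4 * fit.se_intercept)
        assert fit.slope == pytest.approx(-0.031, abs=4 * fit.se_slope)

    def test_slope_invariant_to_moisture_shift(self):
        rng = np.random.default_rng(7)
        w = rng.uniform(0, 30, 100)
        m = 1.0 - 0.03 * w + rng.normal(0, 0.1, 100)
        f1 = fit_moisture_regression(m, w)
        f2 = fit_moisture_regression(m + 5.0, w)
        assert f1.slope == pytest.approx(f2.slope)
        assert f2.intercept == pytest.approx(f1.intercept + 5.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_moisture_regression([1, 2, 3.0], [5, 5, 5.0])


def bird_dataset(n=557, seed=0, intercept=-1.0, slope=0.02, theta=1.5,
                 square_sd=0.8):
    rng = np.random.default_rng(seed)
    c90 = rng.uniform(0, 120, n)
    c04 = np.clip(c90 * rng.uniform(0.7, 1.3, n), 0, None)
    y90, y04 = make_bird_counts(c90, c04, intercept, slope, theta=theta,
                                square_sd=square_sd, seed=seed + 1)
    return pd.DataFrame({"species": "dunlin", "count_1990": y90,
                         "count_2004": y04, "cranefly_1990": c90,
                         "cranefly_2004": c04,
                         "easting": rng.uniform(0, 5e4, n),
                         "northing": rng.uniform(0, 5e4, n)})


class TestBirdGLM:
    def test_recovers_generating_slope(self):
        df = bird_dataset(seed=3)
        fit = fit_bird_glm(df, "dunlin", scope="pooled")
        se = fit.coef.loc["cranefly", "se"]
        # square effect inflates dispersion, not the slope
        assert abs(fit.params["cranefly"] - 0.02) < 3 * se

    def test_single_year_scopes(self):
        df = bird_dataset(seed=4)
        f90 = fit_bird_glm(df, "dunlin", scope="1990")
        f04 = fit_bird_glm(df, "dunlin", scope="2004")
        pooled = fit_bird_glm(df, "dunlin", scope="pooled")
        assert f90.n == f04.n == len(df)
        assert pooled.n == 2 * len(df)

    def test_null_slope_rarely_significant(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            df = bird_dataset(seed=200 + seed, slope=0.0, square_sd=0.3, n=250)
            fit = fit_bird_glm(df, "dunlin", scope="1990")
            if abs(fit.coef.loc["cranefly", "z"]) > 2:
                hits += 1
        assert hits <= 4  # ~5% nominal; allow sampling slack

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            fit_bird_glm(bird_dataset(), "dodo")


class TestBirdGAMCheck:
    def test_unstructured_data_agrees_with_glm(self):
        df = bird_dataset(seed=8, n=400, square_sd=0.3)
        xy = df[["easting", "northing"]].to_numpy()
        out = fit_bird_gam_check(df["count_1990"].to_numpy(),
                                 df["cranefly_1990"].to_numpy(), xy)
        assert out["gam_ok"]
        assert abs(out["gam_coef"] - out["glm_coef"]) < out["glm_se"]

    def test_pure_spatial_gradient_no_cranefly_effect(self):
        rng = np.random.default_rng(10)
        n = 400
        x = rng.uniform(0, 1000, n)
        y = rng.uniform(0, 1000, n)
        counts = rng.poisson(np.exp(0.5 + 0.0015 * x))
        cranefly = rng.uniform(0, 100, n)  # unrelated to counts
        out = fit_bird_gam_check(counts, cranefly, np.column_stack([x, y]))
        assert out["gam_ok"]
        assert abs(out["gam_coef"]) < 3 * out["gam_se"]


class TestYearCorrelation:
    def test_limits(self):
        assert year_correlation([1, 2, 3, 4], [2, 4, 6, 9]) == pytest.approx(1.0)
        assert year_correlation([1, 2, 3, 4], [9, 6, 4, 2]) == pytest.approx(-1.0)

    def test_matches_rank_formula(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 1, 20)
        b = rng.uniform(0, 1, 20)
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        expect = np.corrcoef(ra, rb)[0, 1]
        assert year_correlation(a, b) == pytest.approx(expect)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            year_correlation([1, 1, 1], [2, 3, 4])


class TestPersistence:
    @pytest.mark.parametrize("c90,c04,expect", [
        (0, 0, "empty"), (2, 0, "extinct"), (0, 3, "colonised"),
        (1, 4, "occupied"),
    ])
    def test_definitions(self, c90, c04, expect):
        assert categorize_persistence(c90, c04) == expect

    @given(st.integers(min_value=0, max_value=50),
           st.integers(min_value=0, max_value=50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_total_and_exclusive(self, a, b):
        cat = categorize_persistence(a, b)
        assert cat in ("empty", "extinct", "colonised", "occupied")

    def test_category_counts_partition_squares(self):
        rng = np.random.default_rng(13)
        c90 = rng.poisson(0.8, 557)
        c04 = rng.poisson(0.8, 557)
        cats = [categorize_persistence(a, b) for a, b in zip(c90, c04)]
        assert len(cats) == 557
        from collections import Counter

        assert sum(Counter(cats).values()) == 557


class TestKruskalWallis:
    def test_worked_example(self):
        # direct rank formula: 12/(N(N+1)) * sum R^2/n - 3(N+1)
        h, dof, p = kruskal_wallis([[1, 2], [3, 4]])
        assert h == pytest.approx(2.4)
        assert dof == 1

    def test_four_groups_df(self):
        rng = np.random.default_rng(14)
        groups = [rng.uniform(0, 1, 10) + k for k in range(4)]
        _, dof, p = kruskal_wallis(groups)
        assert dof == 3
        assert p < 0.01

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(15)
        groups = [rng.uniform(0, 1, 8), rng.uniform(0.3, 1.2, 8)]
        h1, _, _ = kruskal_wallis(groups)
        h2, _, _ = kruskal_wallis([np.exp(5 * g) for g in groups])
        assert h1 == pytest.approx(h2)

    def test_two_groups_equals_squared_ranksum_z(self):
        rng = np.random.default_rng(16)
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.4, 1, 70)
        h, _, _ = kruskal_wallis([a, b])
        z = stats.ranksums(a, b).statistic
        assert h == pytest.approx(z ** 2, rel=1e-6)

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])


class TestPairwiseWilcoxon:
    def test_fully_separated_exact_p(self):
        pmat, letters = pairwise_wilcoxon({"lo": [1, 2, 3], "hi": [10, 11, 12]})
        # 3-vs-3 extreme ranks: 2 of C(6,3)=20 assignments are as extreme
        assert pmat.loc["lo", "hi"] == pytest.approx(0.1)
        assert pmat.loc["hi", "lo"] == pmat.loc["lo", "hi"]

    def test_identical_groups_p_near_one(self):
        pmat, letters = pairwise_wilcoxon({"a": [1.0, 2.5, 3.1, 4.7],
                                           "b": [1.0, 2.5, 3.1, 4.7]})
        assert pmat.loc["a", "b"] > 0.9
        assert letters["a"] == letters["b"]

    def test_letters_separate_distant_groups(self):
        rng = np.random.default_rng(17)
        groups = {
            "empty": rng.normal(0, 1, 40),
            "extinct": rng.normal(3, 1, 40),
            "occupied": rng.normal(12, 1, 40),
        }
        _, letters = pairwise_wilcoxon(groups)
        assert len(set(letters.values())) == 3
        assert letters["empty"] == "a"  # lowest group lettered first

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_wilcoxon({"a": [1, 2], "b": []})


class TestProjectBirds:
    def _fit(self):
        return fit_bird_glm(bird_dataset(seed=19), "dunlin", scope="pooled")

    def test_no_change(self):
        fit = self._fit()
        base, fut, pct = project_birds(fit, 50.0, 50.0)
        assert base == fut
        assert pct == 0.0

    def test_less_food_means_decline(self):
        fit = self._fit()
        assert fit.params["cranefly"] > 0
        base, fut, pct = project_birds(fit, 50.0, 20.0)
        assert fut < base
        assert pct > 0

    def test_matches_brute_force_link(self):
        fit = self._fit()
        base, fut, _ = project_birds(fit, 37.0, 11.0)
        eta0 = fit.params["(Intercept)"] + fit.params["cranefly"] * 37.0
        assert base == pytest.approx(np.exp(eta0))
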