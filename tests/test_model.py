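import numpy as np
import pandas as pd
import pytest

from recplast.model import ConvergenceError, PlasticityModel


def normal_dataset(rng, n_pos=3, n_day=3, n_trt=2, n_rep=2, n_fem=3,
                   sigma_rep=0.5, sigma=1.0, effects=None):
    """Gaussian response on the factorial design with replicate intercepts.

    ``effects(pos, day, trt)`` gives the cell mean (default 0).
    """
    rows = []
    for t in range(n_trt):
        trt = f"T{t}"
        for rep in range(n_rep):
            rid = f"{trt}R{rep}"
            u = rng.normal(0.0, sigma_rep)
            for fem in range(n_fem):
                fid = f"{rid}F{fem}"
                for day in range(1, n_day + 1):
                    for pos in range(n_pos):
                        mu = 0.0 if effects is None else effects(pos, day, t)
                        rows.append((fid, rid, trt, day, float(pos), mu + u + rng.normal(0, sigma)))
    return pd.DataFrame(
        rows,
        columns=["female_id", "replicate_id", "treatment", "brood", "midpoint_mb", "cM_per_Mb"],
    )


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(2024)
    df = normal_dataset(rng)
    return df, PlasticityModel.from_rate_table(df).fit()


@pytest.fixture(scope="module")
def pair():
    rng = np.random.default_rng(7)
    df = normal_dataset(rng, sigma_rep=0.0)
    fit = PlasticityModel.from_rate_table(df).fit(fix_lambda=0.0)

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    ols = smf.ols(
        "cM_per_Mb ~ C(midpoint_mb, Sum) * C(treatment, Sum) * C(brood, Sum)",
        data=df,
    ).fit()
    anova = sm.stats.anova_lm(ols, typ=3)
    return df, fit, ols, anova


class TestDegenerateLimit:
    """With the replicate variance forced to 0 the mixed model must collapse
    to ordinary least squares: estimates, F tests and contrasts all match an
    independent fixed-effects implementation."""

    def test_fixed_effects_match_ols(self, pair):
        _, fit, ols, _ = pair
        np.testing.assert_allclose(
            np.sort(fit.fe_params.to_numpy()), np.sort(ols.params.to_numpy()), atol=1e-6
        )

    def test_f_statistics_match_classical_anova(self, pair):
        _, fit, _, anova = pair
        mine = fit.anova()
        theirs = anova.drop(index=["Intercept", "Residual"])
        key = {
            "position": "C(midpoint_mb, Sum)",
            "temperature": "C(treatment, Sum)",
            "day": "C(brood, Sum)",
            "position x temperature": "C(midpoint_mb, Sum):C(treatment, Sum)",
            "position x day": "C(midpoint_mb, Sum):C(brood, Sum)",
            "temperature x day": "C(treatment, Sum):C(brood, Sum)",
            "position x temperature x day": "C(midpoint_mb, Sum):C(treatment, Sum):C(brood, Sum)",
        }
        for term, sm_term in key.items():
            assert mine.loc[term, "F"] == pytest.approx(anova.loc[sm_term, "F"], abs=1e-6)
            assert mine.loc[term, "p_value"] == pytest.approx(
                anova.loc[sm_term, "PR(>F)"], abs=1e-6
            )
            assert mine.loc[term, "den_df"] == pytest.approx(anova.loc["Residual", "df"])

    def test_contrasts_match_cell_mean_differences(self, pair):
        df, fit, _, _ = pair
        contrasts = fit.contrasts(adjust="none")
        cell = df.groupby(["midpoint_mb", "brood", "treatment"])["cM_per_Mb"].mean()
        for _, row in contrasts.iterrows():
            expected = (
                cell.loc[(row["position"], row["day"], "T0")]
                - cell.loc[(row["position"], row["day"], "T1")]
            )
            assert row["estimate"] == pytest.approx(expected, abs=1e-6)


class TestAgainstMixedLM:
    def test_variances_and_estimates_match_statsmodels(self):
        """Independent mixed-model oracle: statsmodels MixedLM REML fit."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(99)
        df = normal_dataset(rng, n_pos=2, n_day=2, n_rep=3, sigma_rep=0.7)
        fit = PlasticityModel.from_rate_table(df).fit()
        sm_fit = smf.mixedlm(
            "cM_per_Mb ~ C(midpoint_mb, Sum) * C(treatment, Sum) * C(brood, Sum)",
            data=df,
            groups=df["replicate_id"],
        ).fit(reml=True)
        assert fit.sigma2 == pytest.approx(sm_fit.scale, rel=1e-4)
        assert fit.sigma2_rep == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-6
        )
        np.testing.assert_allclose(
            np.sort(fit.fe_params.to_numpy()),
            np.sort(sm_fit.fe_params.to_numpy()),
            atol=1e-5,
        )


class TestFitBehaviour:
    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        df = normal_dataset(rng)
        fit1 = PlasticityModel.from_rate_table(df).fit()
        df2 = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = PlasticityModel.from_rate_table(df2).fit()
        pd.testing.assert_series_equal(fit1.fe_params, fit2.fe_params, rtol=1e-8)
        assert fit1.sigma2 == pytest.approx(fit2.sigma2, rel=1e-8)

    def test_location_shift_changes_only_intercept(self):
        rng = np.random.default_rng(6)
        df = normal_dataset(rng)
        f1 = PlasticityModel.from_rate_table(df).fit()
        df2 = df.assign(cM_per_Mb=df["cM_per_Mb"] + 100.0)
        f2 = PlasticityModel.from_rate_table(df2).fit()
        a1, a2 = f1.anova(), f2.anova()
        # tolerance reflects the variance-ratio optimizer's stopping rule,
        # to which between-replicate F statistics are mildly sensitive
        np.testing.assert_allclose(a1["F"], a2["F"], rtol=1e-5)
        assert f2.fe_params["Intercept"] == pytest.approx(f1.fe_params["Intercept"] + 100.0)

    def test_reml_and_ml_fixed_effects_agree_when_balanced(self):
        rng = np.random.default_rng(8)
        df = normal_dataset(rng)
        ss = PlasticityModel.from_rate_table(df)._suffstats
        from recplast.model import _optimise_lambda

        lam_reml, _ = _optimise_lambda(ss, reml=True)
        lam_ml, _ = _optimise_lambda(ss, reml=False)
        _, beta_reml, _ = ss.profiled_neg2(lam_reml, reml=True)
        _, beta_ml, _ = ss.profiled_neg2(lam_ml, reml=False)
        np.testing.assert_allclose(beta_reml, beta_ml, atol=1e-6)

    def test_single_replicate_rejected(self):
        rng = np.random.default_rng(9)
        df = normal_dataset(rng, n_rep=1, n_trt=1)
        with pytest.raises(ValueError, match="replicate"):
            PlasticityModel.from_rate_table(df)

    def test_empty_cell_is_rank_deficient(self):
        rng = np.random.default_rng(10)
        df = normal_dataset(rng)
        cut = df[~((df["midpoint_mb"] == 0.0) & (df["brood"] == 1) & (df["treatment"] == "T0"))]
        with pytest.raises(ValueError, match="rank deficient"):
            PlasticityModel.from_rate_table(cut)

    def test_parameter_recovery_coverage(self):
        """Known fixed effects with sigma_rep^2 = sigma^2 = 1 and large
        cells (50 females per treatment cell over 5 replicates): >= 90% of
        estimated cell contrasts fall within 2 SEs of truth.

        Replicate count matters: the temperature contrast is a
        between-replicate quantity, so its effective df is roughly the
        replicate count and 2-SE coverage only clears 90% with >= ~5
        replicates per arm.
        """
        rng = np.random.default_rng(11)
        hits = total = 0
        true_diff = 1.5  # T0 - T1 at every cell

        def effects(pos, day, t):
            return true_diff if t == 0 else 0.0

        for _ in range(80):
            df = normal_dataset(
                rng, n_pos=2, n_day=2, n_rep=10, n_fem=5, sigma_rep=1.0, sigma=1.0,
                effects=effects,
            )
            fit = PlasticityModel.from_rate_table(df).fit()
            c = fit.contrasts(adjust="none")
            hits += ((c["estimate"] - true_diff).abs() < 2 * c["se"]).sum()
            total += len(c)
        assert hits / total >= 0.90


class TestInference:
    def test_lrt_structure(self, fitted):
        _, fit = fitted
        stat, df, p = fit.lrt_vs_null()
        assert stat >= 0.0
        assert df == len(fit.fe_params) - 1
        assert 0.0 <= p <= 1.0

    def test_lrt_detects_strong_effect(self):
        rng = np.random.default_rng(12)
        df = normal_dataset(
            rng, effects=lambda pos, day, t: 2.0 if (t == 1 and pos == 0) else 0.0
        )
        fit = PlasticityModel.from_rate_table(df).fit()
        _, _, p = fit.lrt_vs_null()
        assert p < 0.01

    def test_anova_terms_and_dfs(self, fitted):
        _, fit = fitted
        an = fit.anova()
        assert list(an.index) == [
            "position", "temperature", "day",
            "position x temperature", "position x day", "temperature x day",
            "position x temperature x day",
        ]
        assert an.loc["position", "num_df"] == 2
        assert an.loc["temperature", "num_df"] == 1
        assert (an["F"] >= 0).all()
        assert (an["den_df"] > 0).all()

    def test_contrast_table_shape_and_adjustment(self, fitted):
        _, fit = fitted
        c_bh = fit.contrasts(adjust="bh")
        c_raw = fit.contrasts(adjust="none")
        assert len(c_bh) == 3 * 3  # positions x days
        assert (c_bh["p_adjusted"] >= c_bh["p_value"] - 1e-12).all()
        np.testing.assert_allclose(c_raw["p_adjusted"], c_raw["p_value"])
        assert (c_bh["se"] > 0).all()

    def test_emmeans_match_cell_means_in_balanced_design(self, fitted):
        df, fit = fitted
        em = fit.emmeans()
        cell = df.groupby(["midpoint_mb", "brood", "treatment"])["cM_per_Mb"].mean()
        for _, row in em.iterrows():
            expected = cell.loc[(row["position"], row["day"], row["temperature"])]
            assert row["emmean"] == pytest.approx(expected, abs=1e-8)

    def test_summary_renders(self, fitted):
        _, fit = fitted
        text = fit.summary()
        assert "REML" in text and "Type-III" in text
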