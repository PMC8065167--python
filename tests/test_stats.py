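"""Mixed-model statistics: OLS equivalences, Satterthwaite df, R², and an
independent cross-check against R's lmerTest implementation."""

import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from onhmorph.stats import (
    GroupComparison,
    SingularDesignError,
    assign_myopia_group,
    fit_lmm,
    group_comparison,
    patient_level_anova,
    patient_level_chi2,
    pearson_corr,
    semi_partial_r2,
)


def clustered_table(rng, n_pat=40, slope=0.45, tau=0.7, sigma=1.0):
    rows = []
    for i in range(n_pat):
        b = rng.normal(0, tau)
        for j in range(2 if i % 3 else 1):
            x = rng.normal(25, 1.2)
            rows.append(
                {
                    "patient_id": f"P{i:03d}",
                    "myopia_group": ["no", "mild", "high"][i % 3],
                    "al_mm": x,
                    "y": 1.0 + slope * x + b + rng.normal(0, sigma),
                }
            )
    return pd.DataFrame(rows)


class TestMyopiaGrouping:
    @pytest.mark.parametrize(
        "al,expected",
        [
            (23.4, "no"),
            (24.0, "no"),  # boundary inclusive on the short side
            (24.0001, "mild"),
            (26.0, "mild"),
            (26.0001, "high"),
            (26.7, "high"),
        ],
    )
    def test_boundaries(self, al, expected):
        assert assign_myopia_group(al) == expected

    def test_missing_flagged(self):
        assert assign_myopia_group(float("nan")) is None

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            assign_myopia_group(-1.0)


class TestLMMDegenerateCases:
    def test_one_eye_per_patient_equals_ols_exactly(self, rng):
        """Without clustering the mixed model collapses to OLS: estimates,
        SEs and df = n − p match to machine precision."""
        n = 60
        t = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "x": rng.normal(0, 1, n),
            }
        )
        t["y"] = 2.0 + 0.5 * t.x + rng.normal(0, 1, n)
        res = fit_lmm(t, "y", ["x"])
        X = sm.add_constant(t[["x"]].to_numpy())
        ols = sm.OLS(t.y.to_numpy(), X).fit()
        assert np.allclose(res.params.to_numpy(), ols.params, atol=1e-10)
        assert np.allclose(res.se.to_numpy(), ols.bse, atol=1e-10)
        assert np.allclose(res.df.to_numpy(), n - 2, atol=1e-6)
        assert res.tau2 == 0.0

    def test_intercept_only_mean_and_df(self, rng):
        n = 30
        t = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n)], "y": rng.normal(5, 2, n)}
        )
        res = fit_lmm(t, "y", [])
        assert res.params.iloc[0] == pytest.approx(t.y.mean(), rel=1e-12)
        assert res.df.iloc[0] == pytest.approx(n - 1, abs=1e-6)

    def test_balanced_zero_residual_matches_patient_mean_ols(self, rng):
        """With residual SD 0 the patient intercept absorbs all spread and
        the fixed estimate equals the patient-mean OLS estimate."""
        b = np.repeat(rng.normal(0, 1, 25), 2)
        t = pd.DataFrame(
            {"patient_id": [f"P{i//2}" for i in range(50)], "y": 3.0 + b}
        )
        res = fit_lmm(t, "y", [])
        assert res.params.iloc[0] == pytest.approx(t.y.mean(), abs=1e-5)
        assert res.sigma2 < 1e-6 * res.tau2

    def test_singular_design_names_aliased_columns(self, rng):
        t = clustered_table(rng)
        t["x2"] = 2 * t["al_mm"]
        with pytest.raises(SingularDesignError, match="x2"):
            fit_lmm(t, "y", ["al_mm", "x2"])

    def test_satterthwaite_df_within_bounds(self, rng):
        t = clustered_table(rng)
        res = fit_lmm(t, "y", ["al_mm"])
        n, p = res.n_eyes, len(res.params)
        assert 0 < res.df["al_mm"] <= n - p + 1e-6
        assert res.tau2 >= 0 and res.sigma2 >= 0

    def test_listwise_missing_reported(self, rng):
        t = clustered_table(rng)
        t.loc[t.index[:5], "al_mm"] = np.nan
        res = fit_lmm(t, "y", ["al_mm"])
        assert res.n_dropped == 5


class TestAgainstLmerTest:
    def test_matches_lmerTest_reference(self, rng, tmp_path):
        """Slope, SE, variance components and Satterthwaite df/p of the
        random-intercept model agree with R lmerTest on the same data."""
        t = clustered_table(rng, n_pat=50)
        csv = tmp_path / "d.csv"
        t.to_csv(csv, index=False)
        rscript = tmp_path / "ref.R"
        rscript.write_text(
            f"""
            suppressMessages(library(lmerTest))
            d <- read.csv('{csv}')
            m <- lmer(y ~ al_mm + (1|patient_id), data=d)
            co <- summary(m)$coefficients['al_mm',]
            vc <- as.data.frame(VarCorr(m))$vcov
            cat(co[['Estimate']], co[['Std. Error']], co[['df']],
                co[['Pr(>|t|)']], vc[1], vc[2], sep='\\n')
            """
        )
        out = subprocess.run(
            ["Rscript", str(rscript)], capture_output=True, text=True, check=True
        )
        est, se, df, p, tau2, sigma2 = map(float, out.stdout.strip().split("\n"))
        res = fit_lmm(t, "y", ["al_mm"])
        assert res.params["al_mm"] == pytest.approx(est, rel=1e-5)
        assert res.se["al_mm"] == pytest.approx(se, rel=1e-4)
        assert res.tau2 == pytest.approx(tau2, rel=1e-3, abs=1e-6)
        assert res.sigma2 == pytest.approx(sigma2, rel=1e-3)
        # expected vs observed REML information: small df discrepancy allowed
        assert res.df["al_mm"] == pytest.approx(df, rel=0.05)
        assert res.pvalues["al_mm"] == pytest.approx(p, rel=0.05, abs=1e-12)


class TestEdwardsR2:
    def test_zero_and_limit(self, rng):
        t = clustered_table(rng)
        res = fit_lmm(t, "y", ["al_mm"])
        r2 = semi_partial_r2(res, "al_mm")
        F = res.ftests.loc["al_mm", "F"]
        nu1, nu2 = res.ftests.loc["al_mm", "df1"], res.ftests.loc["al_mm", "df2"]
        assert r2 == pytest.approx((nu1 / nu2 * F) / (1 + nu1 / nu2 * F), rel=1e-12)
        assert 0 <= r2 <= 1

    def test_printed_precision_case(self):
        # nu1=1, nu2=300, F=34.8 -> 10.4% to printed precision
        x = 1 / 300 * 34.8
        assert round(100 * x / (1 + x), 1) == 10.4

    def test_invariant_to_outcome_rescaling(self, rng):
        t = clustered_table(rng)
        r2a = semi_partial_r2(fit_lmm(t, "y", ["al_mm"]), "al_mm")
        t["y"] = t["y"] * 1000.0
        r2b = semi_partial_r2(fit_lmm(t, "y", ["al_mm"]), "al_mm")
        assert r2a == pytest.approx(r2b, rel=1e-6)

    def test_missing_effect_raises(self, rng):
        res = fit_lmm(clustered_table(rng), "y", ["al_mm"])
        with pytest.raises(KeyError):
            semi_partial_r2(res, "age_yr")


class TestGroupComparison:
    def test_separated_groups_all_pairwise_significant(self, rng):
        """True means 1.7 / 2.0 / 3.4 with small noise: overall and all
        three pairwise comparisons significant."""
        rows = []
        means = {"no": 1.7, "mild": 2.0, "high": 3.4}
        for i in range(90):
            g = ["no", "mild", "high"][i % 3]
            b = rng.normal(0, 0.05)
            for j in range(2):
                rows.append(
                    {
                        "patient_id": f"P{i}",
                        "myopia_group": g,
                        "y": means[g] + b + rng.normal(0, 0.1),
                    }
                )
        cmp_ = group_comparison(pd.DataFrame(rows), "y")
        assert isinstance(cmp_, GroupComparison)
        assert cmp_.overall_p < 1e-6
        assert all(p < 0.05 for p in cmp_.pairwise_p.values())
        assert all(cmp_.significant.values())

    def test_constant_data_never_spuriously_significant(self):
        t = pd.DataFrame(
            {
                "patient_id": [f"P{i//2}" for i in range(40)],
                "myopia_group": ["no", "mild"] * 20,
                "y": np.ones(40),
            }
        )
        cmp_ = group_comparison(t, "y")
        assert np.isnan(cmp_.overall_p) or cmp_.overall_p >= 0.999
        assert not any(cmp_.significant.values())

    def test_single_group_rejected(self, rng):
        t = clustered_table(rng)
        t["myopia_group"] = "no"
        with pytest.raises(ValueError):
            group_comparison(t, "y")


class TestPatientLevel:
    def test_anova_and_chi2(self, rng):
        t = clustered_table(rng, n_pat=60)
        t["age_yr"] = rng.normal(70, 10, len(t))
        t["sex"] = rng.choice(["F", "M"], len(t))
        F, p = patient_level_anova(t, "age_yr")
        assert np.isfinite(F) and 0 <= p <= 1
        chi2, p2 = patient_level_chi2(t, "sex")
        assert np.isfinite(chi2) and 0 <= p2 <= 1


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_corr(x, x)[0] == pytest.approx(1.0)
        assert pearson_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_bivariate_normal_mean_recovery(self, rng):
        """ρ = −0.23 at n = 374: the mean sample r over 500 replicates is
        within Monte-Carlo error of the population value."""
        rho, n = -0.23, 374
        rs = []
        for _ in range(500):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
            rs.append(pearson_corr(z[:, 0], z[:, 1])[0])
        se = (1 - rho**2) / np.sqrt(n - 1)  # per-replicate sd of r
        assert np.mean(rs) == pytest.approx(rho, abs=4 * se / np.sqrt(500))

    @pytest.mark.parametrize(
        "x,y",
        [
            (np.ones(10), np.arange(10.0)),
            (np.arange(3.0), np.arange(4.0)),
            (np.array([1.0, 2.0]), np.array([3.0, 4.0])),
        ],
        ids=["zero_variance", "length_mismatch", "too_short"],
    )
    def test_invalid_inputs(self, x, y):
        with pytest.raises(ValueError):
            pearson_corr(x, y)
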