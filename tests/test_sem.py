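"""Mixed models, piecewise SEM, d-separation and model ranking."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shrubice.sem import (
    MixedModelFit,
    PathDiagram,
    aicc,
    fishers_c,
    fit_mixed_model,
    fit_piecewise_sem,
    rank_models,
)


def _two_level(rng, n_sites=20, n_per=30, beta=0.5, site_sd=1.0, resid_sd=1.0, rho=0.0):
    sites = np.repeat(np.arange(n_sites), n_per)
    x = rng.normal(0, 1, sites.size)
    b = rng.normal(0, site_sd, n_sites)[sites]
    if rho:
        e = np.empty(sites.size)
        for g in range(n_sites):
            z = rng.normal(0, resid_sd, n_per)
            ar = np.empty(n_per)
            ar[0] = z[0]
            for t in range(1, n_per):
                ar[t] = rho * ar[t - 1] + math.sqrt(1 - rho**2) * z[t]
            e[g * n_per : (g + 1) * n_per] = ar
    else:
        e = rng.normal(0, resid_sd, sites.size)
    y = beta * x + b + e
    return pd.DataFrame(
        {"y": y, "x": x, "site": sites, "year": np.tile(np.arange(n_per), n_sites)}
    )


class TestFitMixedModel:
    def test_single_group_matches_ols(self, rng):
        n = 80
        x = rng.normal(0, 1, n)
        y = 1.5 + 0.7 * x + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"y": y, "x": x, "site": 0, "year": np.arange(n)})
        fit = fit_mixed_model(df, "y", ["x"], "site", ar1=False)
        b_ols, a_ols = np.polyfit(x, y, 1)
        assert fit.betas.loc["x", "beta"] == pytest.approx(b_ols, abs=1e-4)
        assert fit.betas.loc["(Intercept)", "beta"] == pytest.approx(a_ols, abs=1e-4)

    def test_perfect_fit_standardized_beta_one(self):
        x = np.linspace(-2, 2, 40)
        df = pd.DataFrame({"y": x.copy(), "x": x, "site": 0, "year": np.arange(40)})
        fit = fit_mixed_model(df, "y", ["x"], "site", ar1=False)
        assert fit.betas.loc["x", "std_beta"] == pytest.approx(1.0, abs=1e-6)
        # variance components stay strictly positive, so R2 approaches 1
        assert fit.r2_marginal == pytest.approx(1.0, abs=0.01)

    def test_matches_statsmodels_mixedlm_ml(self, rng):
        import statsmodels.formula.api as smf

        df = _two_level(rng)
        fit = fit_mixed_model(df, "y", ["x"], "site", ar1=False)
        sm_fit = smf.mixedlm("y ~ x", df, groups=df["site"]).fit(reml=False)
        assert fit.betas.loc["x", "beta"] == pytest.approx(sm_fit.params["x"], abs=1e-5)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        assert fit.betas.loc["x", "se"] == pytest.approx(sm_fit.bse["x"], rel=1e-3)

    def test_matches_r_nlme_with_ar1(self, rng, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = _two_level(rng, n_sites=8, n_per=25, rho=0.4, site_sd=0.8)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            library(nlme)
            df <- read.csv("{csv}")
            m <- lme(y ~ x, random = ~1|site,
                     correlation = corAR1(form = ~year|site), data = df, method = "ML")
            cat(sprintf("%.8f %.6f %.6f", fixef(m)["x"], logLik(m),
                coef(m$modelStruct$corStruct, unconstrained = FALSE)))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout.split()
        beta_r, ll_r, rho_r = map(float, out[-3:])
        fit = fit_mixed_model(df, "y", ["x"], "site", ar1=True)
        assert fit.betas.loc["x", "beta"] == pytest.approx(beta_r, abs=1e-4)
        assert fit.loglik == pytest.approx(ll_r, abs=1e-3)
        assert fit.ar1_rho == pytest.approx(rho_r, abs=1e-3)

    def test_parameter_recovery_two_level(self, rng):
        fit = fit_mixed_model(_two_level(rng), "y", ["x"], "site", ar1=False)
        assert fit.betas.loc["x", "beta"] == pytest.approx(0.5, abs=0.1)
        assert fit.r2_conditional > fit.r2_marginal
        assert fit.sigma_group == pytest.approx(1.0, abs=0.4)

    def test_ar1_rho_recovered(self, rng):
        df = _two_level(rng, n_sites=15, rho=0.5)
        fit = fit_mixed_model(df, "y", ["x"], "site", ar1=True)
        assert fit.ar1_rho == pytest.approx(0.5, abs=0.15)

    def test_containment_df(self, rng):
        df = _two_level(rng, n_sites=13, n_per=30)
        fit = fit_mixed_model(df, "y", ["x"], "site", ar1=False)
        assert fit.betas.loc["x", "df"] == 390 - 13 - 1

    def test_nested_random_intercepts(self, rng):
        df = _two_level(rng, n_sites=10, n_per=40)
        df["shrub"] = df["year"] % 4
        df["y"] = df["y"] + rng.normal(0, 0.8, 10 * 4)[df["site"] * 4 + df["shrub"]]
        fit = fit_mixed_model(df, "y", ["x"], "site", nested="shrub", ar1=False)
        assert fit.sigma_nested > 0.3
        assert fit.grouping == "site/shrub"

    def test_singular_design_errors(self, rng):
        df = _two_level(rng, n_sites=4, n_per=10)
        df["x2"] = df["x"]
        with pytest.raises(ValueError, match="singular"):
            fit_mixed_model(df, "y", ["x", "x2"], "site", ar1=False)


class TestFishersC:
    def test_hand_example(self):
        c, df, p = fishers_c([0.5, 0.5])
        assert c == pytest.approx(-2 * (math.log(0.5) + math.log(0.5)), abs=1e-10)
        assert c == pytest.approx(2.772589, abs=1e-6)
        assert df == 4
        # chi-square survival via the closed-form series for even df
        k = df // 2
        oracle = math.exp(-c / 2) * sum((c / 2) ** i / math.factorial(i) for i in range(k))
        assert p == pytest.approx(oracle, abs=1e-9)

    def test_empty_basis_set(self):
        assert fishers_c([]) == (0.0, 0, 1.0)

    def test_order_invariance(self, rng):
        ps = rng.uniform(0.01, 1, 6)
        c1, _, p1 = fishers_c(ps)
        c2, _, p2 = fishers_c(ps[::-1])
        assert c1 == pytest.approx(c2) and p1 == pytest.approx(p2)

    def test_decreases_as_any_p_increases(self):
        base = [0.2, 0.5]
        c_lo, _, _ = fishers_c(base)
        c_hi, _, _ = fishers_c([0.4, 0.5])
        assert c_hi < c_lo


class TestAicc:
    def test_hand_example(self):
        assert aicc(-100.0, 3, 30) == pytest.approx(206 + 24 / 26, abs=1e-9)

    def test_approaches_aic_for_large_n(self):
        k = 4
        val = aicc(-500.0, k, 10**4 * k + 10)
        assert abs(val - (1000 + 2 * k)) < 0.01

    def test_small_sample_errors(self):
        with pytest.raises(ValueError, match="n > k"):
            aicc(-10.0, 5, 6)


class TestPathDiagram:
    def test_cycle_rejected(self):
        d = PathDiagram.from_strings(["a -> b", "b -> a"])
        with pytest.raises(ValueError, match="cycle"):
            d.topological_order()

    def test_basis_set_of_chain(self):
        # a -> b -> c: single claim c _||_ a | b
        d = PathDiagram.from_strings(["a -> b", "b -> c"])
        assert d.basis_set() == [("a", "c", ("b",))]

    def test_saturated_diagram_empty_basis(self):
        d = PathDiagram.from_strings(["a -> b", "a -> c", "b -> c"])
        assert d.basis_set() == []

    def test_two_exogenous_pair_not_claimed(self):
        d = PathDiagram.from_strings(["a -> c", "b -> c"])
        assert d.basis_set() == []

    def test_conditioning_union_of_parents(self):
        d = PathDiagram.from_strings(["ice -> temp", "ice -> spei", "temp -> rwi", "spei -> rwi"])
        claims = {(x, y): set(c) for x, y, c in d.basis_set()}
        assert claims[("temp", "spei")] == {"ice"}
        assert claims[("ice", "rwi")] == {"temp", "spei"}

    def test_bad_edge_spec(self):
        with pytest.raises(ValueError, match="cause -> effect"):
            PathDiagram.from_strings(["a b"])


def _dag_data(rng, n_sites=10, n_years=30):
    site = np.repeat(np.arange(n_sites), n_years)
    n = site.size
    ice = rng.normal(0, 1, n)
    temp = -0.5 * ice + math.sqrt(1 - 0.25) * rng.normal(0, 1, n)
    spei = 0.5 * ice + math.sqrt(1 - 0.25) * rng.normal(0, 1, n)
    rwi = (
        0.4 * temp
        + 0.3 * spei
        + rng.normal(0, 0.3, n_sites)[site]
        + rng.normal(0, 0.8, n)
    )
    return pd.DataFrame(
        {
            "site": site,
            "year": np.tile(np.arange(n_years), n_sites),
            "ice": ice,
            "temp": temp,
            "spei": spei,
            "rwi": rwi,
        }
    )


_DIAG = PathDiagram.from_strings(
    ["ice -> temp", "ice -> spei", "temp -> rwi", "spei -> rwi"]
)


class TestFitPiecewiseSem:
    def test_saturated_diagram_trivial_fit(self, rng):
        df = _dag_data(rng)
        sat = PathDiagram.from_strings(
            ["ice -> temp", "ice -> spei", "temp -> spei", "ice -> rwi",
             "temp -> rwi", "spei -> rwi"]
        )
        res = fit_piecewise_sem(sat, df, group="site", ar1=False)
        assert res.fisher_c == 0.0
        assert res.dsep_p == 1.0

    def test_path_coefficients_match_standalone_models(self, rng):
        df = _dag_data(rng)
        res = fit_piecewise_sem(_DIAG, df, group="site", ar1=False)
        standalone = fit_mixed_model(df, "rwi", ["temp", "spei"], "site", ar1=False)
        assert res.path_coefficient("temp", "rwi") == pytest.approx(
            standalone.betas.loc["temp", "std_beta"], abs=1e-8
        )

    def test_recovers_generating_paths(self, rng):
        df = _dag_data(rng, n_sites=15, n_years=40)
        res = fit_piecewise_sem(_DIAG, df, group="site", ar1=False)
        assert res.path_coefficient("ice", "temp") == pytest.approx(-0.5, abs=0.1)

    def test_omitted_strong_edge_detected(self, rng):
        # d-separation power: missing edge of standardized strength 0.5
        hits = 0
        for _ in range(20):
            df = _dag_data(rng, n_sites=10, n_years=50)
            missing = PathDiagram.from_strings(
                ["ice -> temp", "ice -> spei", "spei -> rwi"]  # temp -> rwi omitted
            )
            res = fit_piecewise_sem(missing, df, group="site", ar1=False)
            hits += res.dsep_p < 0.05
        assert hits >= 18

    def test_cyclic_diagram_errors(self, rng):
        bad = PathDiagram.from_strings(["ice -> temp", "temp -> ice"])
        with pytest.raises(ValueError, match="cycle"):
            fit_piecewise_sem(bad, _dag_data(rng), group="site")

    def test_missing_node_errors(self, rng):
        d = PathDiagram.from_strings(["nothere -> rwi"])
        with pytest.raises(ValueError, match="nothere"):
            fit_piecewise_sem(d, _dag_data(rng), group="site")


class TestRankModels:
    def test_weights_sum_to_one(self, rng):
        df = _dag_data(rng)
        res = rank_models(
            {"null": [], "temp": ["temp"], "both": ["temp", "spei"]},
            df, "rwi", group="site", ar1=False,
        )
        assert res.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert res.table["delta_aicc"].min() == 0.0

    def test_true_model_beats_null(self, rng):
        wins = 0
        n_rep = 30
        for _ in range(n_rep):
            df = _two_level(rng, n_sites=10, n_per=30, beta=0.5)
            res = rank_models({"null": [], "x": ["x"]}, df, "y", group="site", ar1=False)
            wins += res.best == "x"
        assert wins / n_rep >= 0.95

    def test_needs_two_candidates(self, rng):
        with pytest.raises(ValueError, match="two candidate"):
            rank_models({"null": []}, _dag_data(rng), "rwi", group="site")
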