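"""Mixed-model fitting and AIC selection, cross-checked against lme4."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from pcmckit.mixed_models import (
    GAUSSIAN,
    ModelSpec,
    RankDeficientError,
    collinear_pairs,
    enumerate_and_select,
    fit_mixed,
    lmm_dyadic,
    posterior_sim_pvalues,
    reduced_model_runs,
)
from pcmckit.synthetic_colony import simulate_opportunity_table


def _table(seed=0, n=1500, beta=None, noise=0):
    beta = beta or {"x1": -1.0, "x2": 0.5}
    covs = {k: {"kind": "normal"} for k in beta}
    for j in range(noise):
        covs[f"z{j}"] = {"kind": "normal"}
    return simulate_opportunity_table(
        n, beta, intercept=-0.8, covariates=covs,
        random_effects={"conflict_id": (n // 8, 0.8)}, seed=seed,
    )


class TestBinomialLaplace:
    def test_aic_identity(self):
        df = _table()
        fit = fit_mixed(ModelSpec("outcome", ("x1", "x2")), df)
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * fit.k_params)
        assert fit.k_params == 3 + 1  # intercept + 2 slopes + 1 variance

    def test_likelihood_monotone_under_nesting(self):
        df = _table()
        null = fit_mixed(ModelSpec("outcome", ()), df)
        full = fit_mixed(ModelSpec("outcome", ("x1", "x2")), df)
        assert null.log_likelihood <= full.log_likelihood

    def test_separation_flagged(self):
        df = _table()
        df["outcome"] = 0
        fit = fit_mixed(ModelSpec("outcome", ("x1",)), df)
        assert not fit.converged
        assert fit.params.isna().all()

    def test_rank_deficiency_raises(self):
        df = _table()
        df["dup"] = df["x1"]
        with pytest.raises(RankDeficientError):
            fit_mixed(ModelSpec("outcome", ("x1", "dup")), df)

    def test_non_binary_outcome_rejected(self):
        df = _table()
        df["outcome"] = df["outcome"] + 0.5
        with pytest.raises(ValueError, match="0/1"):
            fit_mixed(ModelSpec("outcome", ("x1",)), df)

    def test_matches_lme4_glmer(self, tmp_path):
        # independent oracle: same model fitted by glmer's Laplace ML
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript with lme4 is part of the supported stack"
        df = _table(seed=7, n=1200)
        csv = tmp_path / "t.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "out.csv"
        script = tmp_path / "fit.R"
        script.write_text(
            f"""suppressMessages(library(lme4))
d <- read.csv("{csv}")
m <- glmer(outcome ~ x1 + x2 + (1|conflict_id), data=d, family=binomial)
co <- summary(m)$coefficients
write.csv(data.frame(est=co[,1], se=co[,2], ll=as.numeric(logLik(m))),
          "{out}", row.names=FALSE)
"""
        )
        subprocess.run([rscript, str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out)
        fit = fit_mixed(ModelSpec("outcome", ("x1", "x2")), df)
        np.testing.assert_allclose(fit.params.to_numpy(), ref["est"], atol=0.02)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref["se"], rtol=0.05)
        assert fit.log_likelihood == pytest.approx(ref["ll"].iloc[0], abs=0.05)

    def test_multi_factor_fit_close_to_single_factor_truth(self):
        df = _table(seed=3, n=1200)
        df["victim_id"] = df["conflict_id"] % 25
        fit = fit_mixed(
            ModelSpec("outcome", ("x1", "x2"),
                      random_effects=("conflict_id", "victim_id")), df)
        assert fit.converged
        assert fit.params["x1"] == pytest.approx(-1.0, abs=0.25)


class TestGaussian:
    def test_zero_variance_response_gives_zero_slopes(self):
        df = _table()
        df["resp"] = 3.14
        fit = fit_mixed(ModelSpec("resp", ("x1",), family=GAUSSIAN), df)
        assert fit.params["x1"] == 0.0
        assert fit.params["intercept"] == pytest.approx(3.14)

    def test_recovers_linear_effect(self):
        rng = np.random.default_rng(5)
        n = 600
        df = pd.DataFrame({
            "kin": rng.integers(0, 2, n).astype(float),
            "noise": rng.standard_normal(n),
            "victim_id": rng.integers(0, 25, n),
            "bystander_id": rng.integers(0, 25, n),
            "group_id": rng.integers(0, 2, n),
        })
        u = rng.normal(0, 5, 25)
        df["tct"] = 10 + 20 * df["kin"] + u[df["victim_id"]] + rng.normal(0, 10, n)
        fit = fit_mixed(
            ModelSpec("tct", ("kin", "noise"), family=GAUSSIAN,
                      random_effects=("victim_id", "bystander_id", "group_id")),
            df,
        )
        assert fit.converged
        assert fit.params["kin"] == pytest.approx(20.0, abs=3.0)
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * fit.k_params)

    def test_posterior_sim_pvalues_stable_in_draws(self):
        rng = np.random.default_rng(8)
        n = 400
        df = pd.DataFrame({
            "kin": rng.integers(0, 2, n).astype(float),
            "victim_id": rng.integers(0, 20, n),
        })
        df["tct"] = 5 * df["kin"] + rng.normal(0, 12, n)
        fit = fit_mixed(ModelSpec("tct", ("kin",), family=GAUSSIAN,
                                  random_effects=("victim_id",)), df)
        p1 = posterior_sim_pvalues(fit, n_draws=10_000, seed=1)["kin"]
        p2 = posterior_sim_pvalues(fit, n_draws=20_000, seed=2)["kin"]
        assert abs(p1 - p2) < 0.02 + 3 * np.sqrt(max(p1, 1e-4) / 10_000)

    def test_dyadic_kin_effect_detected(self):
        detected = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            n = 500
            df = pd.DataFrame({
                "kin": (rng.random(n) < 0.15).astype(float),
                "noise": rng.standard_normal(n),
                "victim_id": rng.integers(0, 30, n),
                "bystander_id": rng.integers(0, 30, n),
                "group_id": rng.integers(0, 2, n),
            })
            df["tct"] = 8 + 20 * df["kin"] + rng.normal(0, 15, n)
            sel, pvals = lmm_dyadic(df, "tct", ["kin", "noise"], seed=rep)
            if ("kin" in sel.best.spec.fixed_effects
                    and sel.best.params["kin"] > 0 and pvals["kin"] < 0.05):
                detected += 1
        assert detected >= 8


class TestSelection:
    def test_single_predictor_pool_fits_two_models(self):
        df = _table()
        sel = enumerate_and_select(df, "outcome", ["x1"])
        assert len(sel.results) == 2

    def test_best_aic_is_minimal(self):
        df = _table(noise=2)
        sel = enumerate_and_select(df, "outcome", ["x1", "x2", "z0", "z1"])
        converged = sel.results[sel.results["converged"]]
        assert sel.best.aic <= converged["aic"].min() + 1e-6

    def test_null_better_than_nothing_on_null_data(self):
        sizes = []
        for rep in range(6):
            df = simulate_opportunity_table(
                500, {}, intercept=-0.5,
                covariates={f"z{j}": {"kind": "normal"} for j in range(4)},
                random_effects={"conflict_id": (60, 0.5)}, seed=300 + rep,
            )
            sel = enumerate_and_select(df, "outcome", [f"z{j}" for j in range(4)])
            sizes.append(len(sel.best.spec.fixed_effects))
        assert np.median(sizes) <= 1

    def test_collinear_pair_blocks_joint_inclusion(self):
        df = _table()
        df["x1_copyish"] = df["x1"] + 0.05 * np.random.default_rng(0).standard_normal(len(df))
        blocked = collinear_pairs(df, ["x1", "x1_copyish", "x2"])
        assert frozenset(("x1", "x1_copyish")) in blocked
        sel = enumerate_and_select(df, "outcome", ["x1", "x1_copyish", "x2"])
        for fx in sel.results["fixed_effects"]:
            assert not {"x1", "x1_copyish"} <= set(fx)

    def test_interactions_require_main_effects(self):
        df = _table()
        df["x1x2"] = 0.0
        with pytest.raises(ValueError, match="interaction"):
            ModelSpec("outcome", ("x1",), interactions=(("x1", "x2"),))
        sel = enumerate_and_select(df, "outcome", ["x1", "x2"],
                                   interactions=[("x1", "x2")])
        with_int = [r for _, r in sel.results.iterrows() if r["interactions"]]
        assert all({"x1", "x2"} <= set(r["fixed_effects"]) for r in with_int)

    def test_lrt_reported_against_null(self):
        df = _table()
        sel = enumerate_and_select(df, "outcome", ["x1", "x2"])
        assert sel.lrt_chi2 == pytest.approx(
            2 * (sel.best.log_likelihood - sel.null.log_likelihood), rel=1e-6)
        assert sel.lrt_p < 0.001  # strong true effects


class TestReducedRuns:
    def test_filter_row_and_bystander_counts(self):
        df = _table(seed=11)
        df["bystander_mother_reared"] = (df.index % 6 == 0).astype(float)
        df["bystander_juvenile"] = 0.0
        df["bystander_id"] = df.index % 36
        red = reduced_model_runs(df, "mother_reared_bystanders",
                                 pool=["x1", "x2"])
        assert red["n_after"] == int((df["bystander_mother_reared"] == 0).sum())

    def test_noop_exclusion_keeps_table(self):
        df = _table(seed=12)
        df["bystander_juvenile"] = 0.0
        df["bystander_id"] = df.index % 36
        red = reduced_model_runs(df, "juvenile_bystanders", pool=["x1", "x2"])
        assert red["n_after"] == len(df)

    def test_emptying_filter_is_error(self):
        df = _table(seed=13)
        df["bystander_juvenile"] = 1.0
        df["bystander_id"] = 0
        with pytest.raises(ValueError, match="every row"):
            reduced_model_runs(df, "juvenile_bystanders", pool=["x1"])
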