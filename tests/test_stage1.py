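"""Per-tract Bayesian additive model: design build, Gibbs sampler, DIC, screen."""

import numpy as np
import pandas as pd
import pytest

from airbw._splines import pspline_basis
from airbw.diagnostics import dic
from airbw.priors import PriorSpec, noninformative_prior
from airbw.stage1 import (MCMCConfig, Stage1Fit, build_design, fit_all_tracts,
                          fit_stage1_tract, residual_moran_screen)

FAST = MCMCConfig(chains=2, iterations=600, burn_in=300, thin=1, seed=0)
WEAK = PriorSpec("weak_normal", 0.0, 100.0, "per ppb")


def linear_data(n, beta, sigma, seed, intercept=3400.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(25.0, 10.0, n)
    y = intercept + beta * x + rng.normal(0.0, sigma, n)
    return pd.DataFrame({"weight": y, "exposure": x})


class TestBuildDesign:
    def test_hand_assembled_matrix_on_small_fixture(self):
        df = pd.DataFrame({
            "weight": [3100.0, 3200, 3300, 3400, 3500, 3600],
            "exposure": [10.0, 20, 30, 10, 20, 30],
            "sex": ["male", "male", "female", "female", "female", "female"],
        })
        d = build_design(df, continuous=(), categorical=("sex",))
        x = df["exposure"].to_numpy()
        expect = np.column_stack([np.ones(6), x - x.mean(),
                                  (df["sex"] == "male").astype(float)])
        assert np.allclose(d.X, expect)
        assert np.allclose(d.y, df["weight"] - df["weight"].mean())

    def test_bspline_rows_sum_to_one_before_centring(self):
        x = np.linspace(0, 1, 80)
        B, K, _ = pspline_basis(x, n_knots=10, degree=3, knot_rule="quantile")
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_spline_block_centred_over_observations(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"weight": rng.normal(3400, 400, 120),
                           "exposure": rng.normal(25, 10, 120),
                           "maternal_age": rng.uniform(18, 42, 120)})
        d = build_design(df, continuous=("maternal_age",), categorical=())
        spline = [b for b in d.blocks if b.kind == "spline"][0]
        assert np.allclose(d.X[:, spline.sl].mean(axis=0), 0.0, atol=1e-12)

    def test_constant_covariate_dropped_with_warning(self):
        df = linear_data(60, -1.0, 100.0, 0).assign(ndvi_500m=0.25)
        with pytest.warns(UserWarning, match="ndvi_500m"):
            d = build_design(df, continuous=("ndvi_500m",), categorical=())
        assert d.dropped == ["ndvi_500m"]

    def test_rank_deficient_factor_named(self):
        df = linear_data(40, -1.0, 100.0, 1)
        df["care"] = ["a", "b"] * 20
        df["dupe"] = df["care"]
        # two identical factors make the second block collinear with the
        # first only jointly; force true rank deficiency via a constant dummy
        df.loc[:, "bad"] = "x"
        d = build_design(df, continuous=(), categorical=("bad",))
        assert "bad" in d.dropped  # single-level factor carries no contrast


class TestGibbsSampler:
    def test_posterior_matches_conjugate_closed_form(self):
        sigma = 60.0
        df = linear_data(300, -1.5, sigma, 5)
        prior = PriorSpec("normal", -3.0, 0.5, "per ppb")
        fit = fit_stage1_tract(df, prior, FAST, sigma_fixed=sigma,
                               continuous=(), categorical=())
        x = df.exposure - df.exposure.mean()
        sxx = float(x @ x)
        b_ls = float(x @ (df.weight - df.weight.mean())) / sxx
        prec = 1 / prior.sd**2 + sxx / sigma**2
        closed = (prior.mean / prior.sd**2 + b_ls * sxx / sigma**2) / prec
        mcse = fit.beta_sd / np.sqrt(fit.beta_draws.size)
        assert abs(fit.beta_mean - closed) < 3 * mcse
        assert fit.beta_sd == pytest.approx(np.sqrt(1 / prec), rel=0.1)

    def test_tight_prior_dominates(self):
        df = linear_data(200, -1.5, 60.0, 6)
        prior = PriorSpec("normal", -3.0, 1e-4, "per ppb")
        fit = fit_stage1_tract(df, prior, FAST, continuous=(), categorical=())
        assert fit.beta_mean == pytest.approx(-3.0, abs=1e-2)

    def test_credible_interval_coverage_over_replicates(self):
        hits = 0
        for rep in range(20):
            df = linear_data(500, -1.5, 450.0, 100 + rep)
            fit = fit_stage1_tract(df, WEAK, FAST, seed=rep,
                                   continuous=(), categorical=())
            lo, hi = np.quantile(fit.beta_draws, [0.025, 0.975])
            hits += lo <= -1.5 <= hi
        assert hits >= 18

    def test_exposure_rescaling_divides_slope_by_ten(self):
        df = linear_data(250, -1.5, 80.0, 8)
        prior = PriorSpec("normal", -1.8, 0.9, "per ppb")
        fit1 = fit_stage1_tract(df, prior, FAST, continuous=(), categorical=())
        df10 = df.assign(exposure=df.exposure * 10.0)
        from airbw.priors import prior_to_model_scale
        fit10 = fit_stage1_tract(df10, prior_to_model_scale(prior, 10.0), FAST,
                                 continuous=(), categorical=())
        # the Gibbs path is exactly equivariant under diagonal rescaling
        assert fit10.beta_mean * 10.0 == pytest.approx(fit1.beta_mean, rel=1e-8)

    def test_log_transform_changes_scale_of_fit(self):
        df = linear_data(200, -1.5, 60.0, 9)
        fit = fit_stage1_tract(df, WEAK, FAST, transform="log",
                               continuous=(), categorical=())
        # slope now on the log-gram scale: around -1.5/3400
        assert abs(fit.beta_mean) < 0.01


class TestDIC:
    def test_degenerate_posterior_has_zero_pd(self):
        d, p, dbar = dic(np.full(200, 123.4), 123.4)
        assert p == pytest.approx(0.0, abs=1e-10)
        assert d == pytest.approx(dbar) == pytest.approx(123.4)

    def test_effective_parameters_near_k_for_known_sigma(self):
        sigma = 50.0
        rng = np.random.default_rng(10)
        n = 2000
        df = pd.DataFrame({
            "exposure": rng.normal(25, 10, n),
            "ethnicity": rng.choice(["a", "b", "c"], n),
        })
        df["weight"] = (3400 - 1.5 * df.exposure
                        + 40.0 * (df.ethnicity == "b")
                        - 25.0 * (df.ethnicity == "c")
                        + rng.normal(0, sigma, n))
        cfg = MCMCConfig(chains=3, iterations=1400, burn_in=400, thin=1, seed=3)
        fit = fit_stage1_tract(df, WEAK, cfg, sigma_fixed=sigma,
                               continuous=(), categorical=("ethnicity",))
        assert fit.pD == pytest.approx(4.0, abs=0.5)  # intercept+slope+2 dummies

    def test_pure_noise_covariate_increases_pd(self):
        rng = np.random.default_rng(11)
        df = linear_data(400, -1.5, 100.0, 11)
        df["ndvi_500m"] = rng.uniform(0, 0.6, 400)  # unrelated to outcome
        cfg = MCMCConfig(chains=2, iterations=1000, burn_in=400, thin=1, seed=4)
        base = fit_stage1_tract(df, WEAK, cfg, continuous=(), categorical=())
        extra = fit_stage1_tract(df, WEAK, cfg, continuous=("ndvi_500m",),
                                 categorical=())
        assert extra.pD > base.pD

    def test_correct_transform_attains_lower_dic(self):
        # multiplicative (log-scale) truth: the log fit should beat the
        # misspecified identity fit, Jacobian-corrected DIC comparison
        cfg = MCMCConfig(chains=2, iterations=800, burn_in=300, thin=1, seed=5)
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(200 + rep)
            x = rng.normal(25.0, 10.0, 400)
            y = np.exp(np.log(3400.0) - 0.004 * x + rng.normal(0, 0.15, 400))
            df = pd.DataFrame({"weight": y, "exposure": x})
            ident = fit_stage1_tract(df, WEAK, cfg, seed=rep,
                                     continuous=(), categorical=())
            logged = fit_stage1_tract(df, WEAK, cfg, seed=rep, transform="log",
                                      continuous=(), categorical=())
            wins += logged.dic < ident.dic
        assert wins >= 8


class TestResidualScreen:
    @staticmethod
    def _fits_and_births(residual_fn, n_tracts=60, n=50, seed=0):
        rng = np.random.default_rng(seed)
        fits, frames = {}, []
        for t in range(n_tracts):
            coords = rng.uniform(0, 2, size=(n, 2))
            res = residual_fn(rng, coords)
            tid = f"t{t}"
            fits[tid] = Stage1Fit(tid, 0.0, 1.0, np.zeros(10), 0, 0, 0,
                                  1.0, True, res, n)
            frames.append(pd.DataFrame({"tract_id": tid, "x_km": coords[:, 0],
                                        "y_km": coords[:, 1]}))
        return fits, pd.concat(frames, ignore_index=True)

    def test_independent_residuals_are_mostly_nonsignificant(self):
        fits, births = self._fits_and_births(
            lambda rng, c: rng.normal(0, 1, len(c)), n_tracts=100)
        _, frac = residual_moran_screen(fits, births)
        assert 0.85 <= frac <= 1.0

    def test_strong_gradient_detected_and_permutation_is_not(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 2, size=(80, 2))
        grad = coords[:, 0] + 0.05 * rng.normal(size=80)
        fits = {"t0": Stage1Fit("t0", 0, 1, np.zeros(10), 0, 0, 0, 1.0, True,
                                grad, 80)}
        births = pd.DataFrame({"tract_id": "t0", "x_km": coords[:, 0],
                               "y_km": coords[:, 1]})
        table, frac = residual_moran_screen(fits, births)
        assert table["moran_p"].iloc[0] < 0.05 and frac == 0.0
        fits["t0"].residuals = rng.permutation(grad)
        table2, _ = residual_moran_screen(fits, births)
        assert table2["moran_p"].iloc[0] >= 0.05

    def test_small_tract_skipped_with_warning(self):
        fits, births = self._fits_and_births(
            lambda rng, c: rng.normal(0, 1, len(c)), n_tracts=2, n=5)
        with pytest.warns(UserWarning, match="skipped"):
            table, _ = residual_moran_screen(fits, births)
        assert len(table) == 0


class TestFitAllTracts:
    def test_identical_data_identical_summaries_and_recovery(self):
        rng = np.random.default_rng(21)
        frames = []
        for t in range(6):
            df = linear_data(150, -1.5, 200.0, 300 + t)
            df["tract_id"] = f"t{t}"
            frames.append(df)
        births = pd.concat(frames, ignore_index=True)
        tracts = pd.DataFrame({"tract_id": [f"t{t}" for t in range(6)]})
        res = fit_all_tracts(births, tracts, WEAK, FAST,
                             continuous=(), categorical=())
        res2 = fit_all_tracts(births, tracts, WEAK, FAST,
                              continuous=(), categorical=())
        assert res.summary == res2.summary  # seed-derived determinism
        s = res.summary
        assert abs(s["mean_effect"] - (-1.5)) < 3 * s["se"] + 0.05
        assert s["ci_low"] < s["mean_effect"] < s["ci_high"]

    def test_ci_widens_when_births_subsampled(self):
        rng = np.random.default_rng(22)
        big, small = [], []
        for t in range(5):
            df = linear_data(500, -1.5, 300.0, 400 + t)
            df["tract_id"] = f"t{t}"
            big.append(df)
            small.append(df.iloc[:50])
        tracts = pd.DataFrame({"tract_id": [f"t{t}" for t in range(5)]})
        r_big = fit_all_tracts(pd.concat(big), tracts, WEAK, FAST,
                               continuous=(), categorical=())
        r_small = fit_all_tracts(pd.concat(small), tracts, WEAK, FAST,
                                 continuous=(), categorical=())
        assert (r_small.summary["ci_high"] - r_small.summary["ci_low"]
                > r_big.summary["ci_high"] - r_big.summary["ci_low"])


def test_mcmc_config_invariants():
    with pytest.raises(ValueError):
        MCMCConfig(iterations=100, burn_in=100)
    with pytest.raises(ValueError):
        MCMCConfig(chains=1)  # PSRF requested by default
    MCMCConfig(chains=1, psrf_gate=None)  # allowed when the gate is off
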