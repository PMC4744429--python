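"""Tract-level structured additive model: P-splines, CAR Gibbs, summaries."""

import numpy as np
import pandas as pd
import pytest

from airbw._splines import pspline_basis
from airbw.diagnostics import gelman_rubin
from airbw.stage1 import MCMCConfig
from airbw.stage2 import (SmoothPosterior, adverse_probability, detect_threshold,
                          fit_stage2, quartile_contrast, variance_decomposition)
from conftest import synthetic_stage2_inputs

FAST = MCMCConfig(chains=2, iterations=800, burn_in=400, thin=2, seed=0)


def linear_smooth_posterior(slope, x_obs, jitter=1e-6, ndraws=400, seed=0):
    """Posterior whose every draw is (almost exactly) the line slope*x."""
    B, _, knots = pspline_basis(x_obs, n_knots=8, degree=3)
    theta, *_ = np.linalg.lstsq(B, slope * x_obs, rcond=None)
    rng = np.random.default_rng(seed)
    draws = theta + jitter * rng.standard_normal((ndraws, theta.size))
    return SmoothPosterior("lin", knots, 3, draws, x_obs)


class TestPsplineBasis:
    def test_rw2_penalty_null_space(self):
        _, K, _ = pspline_basis(np.linspace(0, 1, 60), n_knots=12, penalty_order=2)
        ev = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(ev) < 1e-10) == 2
        assert ev.min() > -1e-10  # positive semidefinite

    def test_partition_of_unity(self):
        B, _, _ = pspline_basis(np.linspace(-3, 7, 50), n_knots=9)
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_cubic_basis_reproduces_quadratic(self):
        x = np.linspace(0, 2, 80)
        B, _, _ = pspline_basis(x, n_knots=10, degree=3)
        theta, *_ = np.linalg.lstsq(B, x**2, rcond=None)
        assert np.allclose(B @ theta, x**2, atol=1e-10)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            pspline_basis(np.array([0.0, 1.0, 2.0] * 10), n_knots=10)


class TestFitStage2:
    def test_meta_analytic_limit(self, lattice15):
        # smooths and spatial field off: alpha0 is the V-weighted mean
        table, tracts, W, truth, _ = synthetic_stage2_inputs(0, lattice15)
        fit = fit_stage2(table, tracts, W, FAST, smooth_covariates=[],
                         include_spatial=False)
        w = 1.0 / table["beta_sd"] ** 2
        closed = float(np.sum(w * table["beta_mean"]) / np.sum(w))
        mcse = fit.alpha0_draws.std() / np.sqrt(fit.alpha0_draws.size)
        assert abs(fit.alpha0_draws.mean() - closed) < 3 * mcse

    def test_alpha0_reported_scale_is_exactly_ten_times_internal(self, lattice15):
        table, tracts, W, truth, _ = synthetic_stage2_inputs(1, lattice15)
        fit = fit_stage2(table, tracts, W, FAST, smooth_covariates=[],
                         include_spatial=False)
        assert fit.alpha0_per10()["mean"] == 10.0 * fit.alpha0_draws.mean()

    def test_rho_zero_limit_gives_uncorrelated_field(self, lattice15):
        # truth has an independent (rho=0) field; fit with rho fixed at ~0
        table, tracts, W, truth, _ = synthetic_stage2_inputs(
            2, lattice15, noise_sd=0.05,
            sim_kwargs={"rho_true": 0.0, "tau_sp": 1.0, "smooth_specs": []})
        fit = fit_stage2(table, tracts, W, FAST, smooth_covariates=[],
                         rho_fixed=0.0)
        phi = fit.phi_draws.mean(axis=0)
        rows, cols = W.W.nonzero()
        keep = rows < cols
        r = np.corrcoef(phi[rows[keep]], phi[cols[keep]])[0, 1]
        assert abs(r) < 0.1

    def test_zero_spatial_truth_shrinks_tau(self, lattice15):
        both = ["pct_drive_to_work", "pct_heavy_industry"]
        table0, tracts0, W, _, _ = synthetic_stage2_inputs(
            3, lattice15, noise_sd=0.1, sim_kwargs={"tau_sp": 0.0})
        table1, tracts1, _, _, _ = synthetic_stage2_inputs(
            3, lattice15, noise_sd=0.1, sim_kwargs={"tau_sp": 0.8})
        f0 = fit_stage2(table0, tracts0, W, FAST, smooth_covariates=both)
        f1 = fit_stage2(table1, tracts1, W, FAST, smooth_covariates=both)
        assert np.median(f0.tau2_draws) < 0.25 * np.median(f1.tau2_draws)

    def test_misaligned_tracts_rejected(self, lattice15):
        table, tracts, W, _, _ = synthetic_stage2_inputs(4, lattice15)
        with pytest.raises(ValueError, match="align"):
            fit_stage2(table.iloc[:-5], tracts, W, FAST)


class TestGelmanRubin:
    def test_formula_oracle_on_fixed_arrays(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(2, 100))
        m, n = chains.shape
        means = chains.mean(axis=1)
        W = chains.var(axis=1, ddof=1).mean()
        B = n * means.var(ddof=1)
        expect = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert gelman_rubin(chains) == pytest.approx(expect, abs=1e-12)

    def test_shuffled_copies_of_one_sample_mix_perfectly(self):
        rng = np.random.default_rng(1)
        pooled = rng.normal(size=400)
        chains = np.stack([rng.permutation(pooled)[:200] for _ in range(4)])
        assert gelman_rubin(chains) <= 1.01

    def test_disjoint_constant_chains_flagged_infinite(self):
        chains = np.stack([np.zeros(50), np.ones(50)])
        assert gelman_rubin(chains) == np.inf

    def test_vectorised_parameter_axis(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(3, 80, 5))
        out = gelman_rubin(chains)
        assert out.shape == (5,)
        assert np.allclose(out[0], gelman_rubin(chains[:, :, 0]))


class TestQuartileContrast:
    def test_linear_smooth_identity(self):
        # q4 - q1 = 2 for x in [0,4]; contrast = 10 * a * 2
        x = np.linspace(0.0, 4.0, 101)
        sm = linear_smooth_posterior(slope=0.7, x_obs=x)
        out = quartile_contrast(sm)
        assert out["contrast_mean"] == pytest.approx(20 * 0.7, rel=1e-3)

    def test_constant_smooth_degenerate_interval(self):
        x = np.linspace(0.0, 1.0, 60)
        sm = linear_smooth_posterior(slope=0.0, x_obs=x, jitter=1e-12)
        out = quartile_contrast(sm)
        assert out["contrast_mean"] == pytest.approx(0.0, abs=1e-8)
        assert out["ci_high"] - out["ci_low"] < 1e-8

    def test_constant_covariate_rejected(self):
        sm = linear_smooth_posterior(0.5, np.linspace(0, 1, 60))
        sm.x_obs = np.full(60, 0.3)
        with pytest.raises(ValueError, match="constant"):
            quartile_contrast(sm)


class TestDetectThreshold:
    def test_linear_smooth_has_no_onset(self):
        sm = linear_smooth_posterior(2.0, np.linspace(0, 1, 80), jitter=1e-8)
        assert detect_threshold(sm) is None

    def test_flat_smooth_has_no_onset(self):
        sm = linear_smooth_posterior(0.0, np.linspace(0, 1, 80), jitter=1e-4)
        assert detect_threshold(sm) is None

    def test_knee_recovered_from_exact_posterior(self):
        x = np.linspace(0.0, 0.3, 120)
        B, _, knots = pspline_basis(x, n_knots=12, degree=3)
        truth = -10.0 * np.maximum(x - 0.18, 0.0)
        theta, *_ = np.linalg.lstsq(B, truth, rcond=None)
        rng = np.random.default_rng(3)
        # realistic coefficient uncertainty, so the onset interval reflects
        # the spline's resolution of the corner
        draws = theta + 2e-2 * rng.standard_normal((500, theta.size))
        sm = SmoothPosterior("knee", knots, 3, draws, x)
        interval = detect_threshold(sm)
        assert interval is not None
        lo, hi = interval
        assert lo <= 0.18 <= hi


class TestVarianceDecomposition:
    def test_shares_sum_to_one(self, lattice15):
        table, tracts, W, _, _ = synthetic_stage2_inputs(5, lattice15)
        fit = fit_stage2(table, tracts, W, FAST,
                         smooth_covariates=["pct_drive_to_work"])
        shares = variance_decomposition(fit)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-10)
        assert all(0.0 <= v <= 1.0 for v in shares.values())

    def test_strong_field_no_smooth_truth_gives_spatial_majority(self, lattice15):
        table, tracts, W, _, _ = synthetic_stage2_inputs(
            6, lattice15, noise_sd=0.1,
            sim_kwargs={"tau_sp": 1.2, "smooth_specs": []})
        fit = fit_stage2(table, tracts, W, FAST,
                         smooth_covariates=["pct_drive_to_work"])
        assert variance_decomposition(fit)["spatial"] > 0.5


class TestAdverseProbability:
    def test_all_negative_draws(self):
        assert np.all(adverse_probability(-np.abs(np.random.default_rng(0)
                                                  .normal(size=(200, 4)))) == 1.0)

    def test_symmetric_draws_near_half(self):
        draws = np.random.default_rng(1).normal(size=(4000, 6))
        assert np.allclose(adverse_probability(draws), 0.5, atol=0.03)

    def test_matches_brute_force_count(self):
        draws = np.random.default_rng(2).normal(size=(200, 3))
        expect = np.array([sum(draws[i, j] < 0 for i in range(200)) / 200
                           for j in range(3)])
        assert np.allclose(adverse_probability(draws), expect)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            adverse_probability(np.zeros((50, 3)))
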