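"""Stage two: tract-level structured additive model with CAR spatial residuals.

The per-tract pollutant slopes estimated in stage one (with their posterior
variances, treated as known measurement variances) are regressed on tract
covariates:

    beta_hat_c ~ N(eta_c, V_c),
    eta_c = alpha_0 + sum_j s(c_jc) + eps_c,

where each s() is a penalized B-spline (P-spline) with a random-walk
penalty, and eps is a proper conditional-autoregressive (CAR) field with
precision tau^-2 (D - rho W) on binary rook weights. alpha_0 is the
population-average pollutant effect (reported in g per 10 ppb); the smooths
describe how tract-level factors attenuate or exacerbate the effect; the
CAR field absorbs residual spatial clustering. All updates are conjugate
except rho, which is sampled by griddy Gibbs on its admissible interval.
Identifiability: each smooth and the spatial field are centred every sweep,
with alpha_0 absorbing the level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from ._splines import bspline_design, bspline_derivative_design, pspline_basis
from .diagnostics import gelman_rubin
from .spatial import SpatialWeights, car_rho_interval
from .stage1 import MCMCConfig

__all__ = [
    "SmoothPosterior",
    "Stage2Fit",
    "pspline_basis",
    "fit_stage2",
    "gelman_rubin",
    "quartile_contrast",
    "detect_threshold",
    "variance_decomposition",
    "adverse_probability",
]

_IG_A = 0.001
_IG_B = 0.001
_ALPHA_PREC = 1e-6


@dataclass
class SmoothPosterior:
    """Posterior of one P-spline smooth: coefficient draws plus basis metadata."""

    name: str
    knots: np.ndarray
    degree: int
    theta_draws: np.ndarray  # (ndraws, p), centred over observed tracts
    x_obs: np.ndarray

    def curves(self, xgrid: np.ndarray) -> np.ndarray:
        """Smooth evaluated on a grid for every draw, shape (ndraws, grid)."""
        B = bspline_design(xgrid, self.knots, self.degree)
        return self.theta_draws @ B.T

    def derivative_curves(self, xgrid: np.ndarray) -> np.ndarray:
        G = bspline_derivative_design(xgrid, self.knots, self.degree,
                                      self.theta_draws.shape[1])
        return self.theta_draws @ G.T

    def curve_summary(self, grid_size: int = 100) -> pd.DataFrame:
        xg = np.linspace(self.x_obs.min(), self.x_obs.max(), grid_size)
        c = self.curves(xg)
        return pd.DataFrame({
            "x": xg, "mean": c.mean(axis=0),
            "lo": np.quantile(c, 0.025, axis=0),
            "hi": np.quantile(c, 0.975, axis=0),
        })


@dataclass
class Stage2Fit:
    """Pooled posterior of the tract-level model (internal scale: g per ppb)."""

    tract_ids: np.ndarray
    alpha0_draws: np.ndarray
    smooths: dict
    phi_draws: np.ndarray  # (ndraws, n) spatial field; zeros when disabled
    eta_draws: np.ndarray  # (ndraws, n) per-tract effect
    rho_draws: np.ndarray
    tau2_draws: np.ndarray
    beta_hat: np.ndarray
    V: np.ndarray
    psrf: dict
    converged: bool

    def alpha0_per10(self) -> dict:
        """Overall effect on the reporting scale: exactly 10x the per-ppb draws."""
        d = 10.0 * self.alpha0_draws
        return {"mean": float(d.mean()),
                "ci_low": float(np.quantile(d, 0.025)),
                "ci_high": float(np.quantile(d, 0.975))}

    def summary(self) -> dict:
        out = {"alpha0_g_per_10ppb": self.alpha0_per10(),
               "psrf": self.psrf, "converged": self.converged,
               "variance_shares": variance_decomposition(self)}
        if self.rho_draws.size:
            out["rho_mean"] = float(self.rho_draws.mean())
            out["tau_mean"] = float(np.sqrt(self.tau2_draws).mean())
        return out


def fit_stage2(stage1_table: pd.DataFrame, tracts: pd.DataFrame,
               weights: SpatialWeights, mcmc: MCMCConfig,
               smooth_covariates: list[str] | None = None,
               n_knots: int = 20, degree: int = 3, penalty_order: int = 2,
               include_spatial: bool = True, v_inflation: float = 1.0,
               rho_fixed: float | None = None) -> Stage2Fit:
    """Fit the structured additive model by blocked Gibbs sampling.

    ``stage1_table`` provides tract_id, beta_mean (the response, g per ppb)
    and beta_sd (whose square, optionally inflated by ``v_inflation``, is
    the known measurement variance V). ``smooth_covariates`` names the
    tract columns modelled with P-splines (20 equidistant interior knots,
    cubic, second-order random-walk penalty); an empty list plus
    ``include_spatial=False`` reduces the model to a fixed-effects
    meta-analysis of the slopes. Chains are pooled after burn-in; PSRF is
    reported per parameter block.
    """
    merged = tracts[["tract_id"]].merge(stage1_table, on="tract_id", how="inner")
    if len(merged) != len(tracts):
        raise ValueError("stage-one fits and tract table do not align")
    if list(weights.ids) != list(tracts["tract_id"]):
        raise ValueError("weights ids must align with tract table order")
    beta_hat = merged["beta_mean"].to_numpy(float)
    V = merged["beta_sd"].to_numpy(float) ** 2 * v_inflation
    if (V <= 0).any():
        raise ValueError("measurement variances must be > 0")
    Vinv = 1.0 / V
    n = beta_hat.size
    smooth_covariates = list(smooth_covariates or [])

    bases = []
    for name in smooth_covariates:
        x = tracts[name].to_numpy(float)
        nk = min(n_knots, max(1, np.unique(x).size - degree - 1))
        B, K, knots = pspline_basis(x, n_knots=nk, degree=degree,
                                    penalty_order=penalty_order,
                                    knot_rule="equidistant")
        rank = B.shape[1] - penalty_order
        bases.append({"name": name, "B": B, "K": K, "knots": knots, "x": x,
                      "rank": rank, "BtVinv": B.T * Vinv})

    if include_spatial:
        D = weights.D
        if (D == 0).any():
            raise ValueError("island tracts present; filter them before stage two")
        W = weights.W.toarray()
        s = 1.0 / np.sqrt(D)
        lam = np.linalg.eigvalsh(W * s[:, None] * s[None, :])
        lo, hi = 1.0 / lam.min(), 1.0 / lam.max()
        eps = 1e-3 * (hi - lo)
        rho_grid = np.linspace(lo + eps, hi - eps, 101)
        if rho_fixed is not None and not (lo < rho_fixed < hi):
            raise ValueError(f"rho_fixed={rho_fixed} outside admissible "
                             f"interval ({lo:.4f}, {hi:.4f})")
        # log-determinant term of (D - rho W), up to a rho-free constant
        logdet_grid = 0.5 * np.log1p(-np.outer(rho_grid, lam)).sum(axis=1)
        Dmat = np.diag(D)

    keep_per_chain = (mcmc.iterations - mcmc.burn_in + mcmc.thin - 1) // mcmc.thin
    chains_alpha = np.empty((mcmc.chains, keep_per_chain))
    chains_tau2 = np.empty((mcmc.chains, keep_per_chain))
    chains_rho = np.empty((mcmc.chains, keep_per_chain))
    chains_contrast = {b["name"]: np.empty((mcmc.chains, keep_per_chain)) for b in bases}
    all_alpha, all_phi, all_eta, all_rho, all_tau2 = [], [], [], [], []
    all_theta = {b["name"]: [] for b in bases}

    for ch in range(mcmc.chains):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=mcmc.seed,
                                                           spawn_key=(500 + ch,)))
        alpha0 = float(np.sum(Vinv * beta_hat) / np.sum(Vinv))
        thetas = [np.zeros(b["B"].shape[1]) for b in bases]
        delta2 = np.ones(len(bases))
        phi = np.zeros(n)
        tau2 = 0.1
        rho = 0.0 if rho_fixed is None else float(rho_fixed)
        smooth_fit = np.zeros(n)
        k = 0
        for it in range(mcmc.iterations):
            if not include_spatial:
                r = beta_hat - smooth_fit - phi
                prec = float(np.sum(Vinv)) + _ALPHA_PREC
                alpha0 = rng.normal(float(np.sum(Vinv * r)) / prec, 1.0 / np.sqrt(prec))
            # P-spline blocks
            for j, b in enumerate(bases):
                fit_j = b["B"] @ thetas[j]
                r = beta_hat - alpha0 - (smooth_fit - fit_j) - phi
                A = b["BtVinv"] @ b["B"] + b["K"] / delta2[j]
                rhs = b["BtVinv"] @ r
                c, low = cho_factor(A, lower=True)
                mean = cho_solve((c, low), rhs)
                th = mean + solve_triangular(c, rng.standard_normal(mean.size),
                                             lower=True, trans="T")
                new_fit = b["B"] @ th
                centre = float(new_fit.mean())
                th = th - centre  # partition of unity: shifts fitted values by -centre
                alpha0 += centre
                smooth_fit += (new_fit - centre) - fit_j
                thetas[j] = th
                quad = float(th @ b["K"] @ th)
                delta2[j] = 1.0 / rng.gamma(_IG_A + b["rank"] / 2.0,
                                            1.0 / (_IG_B + quad / 2.0))
            # joint (alpha0, spatial field) block: the proper CAR prior
            # identifies the field's level, so sampling the intercept jointly
            # with the field propagates the field-mean uncertainty into
            # alpha0 and removes the strong Gibbs correlation between them
            if include_spatial:
                Q = (Dmat - rho * W) / tau2
                A = np.empty((n + 1, n + 1))
                A[0, 0] = float(np.sum(Vinv)) + _ALPHA_PREC
                A[0, 1:] = Vinv
                A[1:, 0] = Vinv
                A[1:, 1:] = Q + np.diag(Vinv)
                r = Vinv * (beta_hat - smooth_fit)
                rhs = np.concatenate([[r.sum()], r])
                c, low = cho_factor(A, lower=True)
                mean = cho_solve((c, low), rhs)
                draw = mean + solve_triangular(c, rng.standard_normal(n + 1),
                                               lower=True, trans="T")
                alpha0, phi = float(draw[0]), draw[1:]
                qD = float(phi @ (D * phi))
                qW = float(phi @ (W @ phi))
                quad = qD - rho * qW
                tau2 = 1.0 / rng.gamma(_IG_A + n / 2.0, 1.0 / (_IG_B + quad / 2.0))
                if rho_fixed is None:
                    # griddy Gibbs for rho on its admissible interval (uniform prior)
                    logp = logdet_grid - (qD - rho_grid * qW) / (2.0 * tau2)
                    logp -= logp.max()
                    w = np.exp(logp)
                    rho = float(rng.choice(rho_grid, p=w / w.sum()))
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                chains_alpha[ch, k] = alpha0
                chains_tau2[ch, k] = tau2
                chains_rho[ch, k] = rho
                all_alpha.append(alpha0)
                all_phi.append(phi.copy())
                all_eta.append(alpha0 + smooth_fit + phi)
                all_rho.append(rho)
                all_tau2.append(tau2)
                for j, b in enumerate(bases):
                    all_theta[b["name"]].append(thetas[j].copy())
                    q1, q3 = np.quantile(b["x"], [0.25, 0.75])
                    Bq = bspline_design(np.array([q1, q3]), b["knots"], degree)
                    sv = Bq @ thetas[j]
                    chains_contrast[b["name"]][ch, k] = sv[1] - sv[0]
                k += 1

    smooths = {
        b["name"]: SmoothPosterior(b["name"], b["knots"], degree,
                                   np.array(all_theta[b["name"]]), b["x"])
        for b in bases
    }
    psrf = {"alpha0": float(gelman_rubin(chains_alpha)) if mcmc.chains >= 2 else np.nan}
    if mcmc.chains >= 2:
        if include_spatial:
            psrf["tau2"] = float(gelman_rubin(chains_tau2))
            psrf["rho"] = float(gelman_rubin(chains_rho))
        for name, arr in chains_contrast.items():
            psrf[f"smooth:{name}"] = float(gelman_rubin(arr))
    gate = mcmc.psrf_gate
    finite = [v for v in psrf.values() if np.isfinite(v)]
    converged = bool(gate is None or all(v <= gate for v in finite))
    return Stage2Fit(
        tract_ids=tracts["tract_id"].to_numpy(),
        alpha0_draws=np.asarray(all_alpha),
        smooths=smooths,
        phi_draws=np.asarray(all_phi),
        eta_draws=np.asarray(all_eta),
        rho_draws=np.asarray(all_rho) if include_spatial else np.empty(0),
        tau2_draws=np.asarray(all_tau2) if include_spatial else np.empty(0),
        beta_hat=beta_hat, V=V, psrf=psrf, converged=converged)


def quartile_contrast(smooth: SmoothPosterior, per_unit: float = 10.0) -> dict:
    """Change in pollutant effect between covariate quartiles, g per 10 ppb.

    Evaluates 10 * (s(q3) - s(q1)) per posterior draw at the covariate's
    25th and 75th percentiles; the smooth's centring cancels in the
    difference.
    """
    x = smooth.x_obs
    q1, q3 = np.quantile(x, [0.25, 0.75])
    if q3 == q1:
        raise ValueError(f"covariate {smooth.name!r} is constant across tracts")
    c = smooth.curves(np.array([q1, q3]))
    draws = per_unit * (c[:, 1] - c[:, 0])
    return {"covariate": smooth.name, "q1": float(q1), "q4": float(q3),
            "contrast_mean": float(draws.mean()),
            "ci_low": float(np.quantile(draws, 0.025)),
            "ci_high": float(np.quantile(draws, 0.975)),
            "draws": draws}


def detect_threshold(smooth: SmoothPosterior, grid_size: int = 201,
                     full_span_fraction: float = 0.95) -> tuple[float, float] | None:
    """Approximate onset interval where a smooth starts changing markedly.

    The derivative of the smooth is computed analytically from the B-spline
    basis on a grid. The onset of "pronounced" influence is where the
    derivative magnitude first exceeds and stays above half its maximum;
    the reported interval is the central 95 % of the posterior distribution
    of that crossing location, evaluated per draw and anchored at the most
    credibly steep grid point (wide-band boundary wiggles cannot anchor
    it). Returns None when the pointwise 95 % band of the derivative
    includes zero everywhere (no evidence of change) or when the half-
    maximum region spans essentially the whole domain (a constant
    derivative, e.g. a linear smooth, has no onset).
    """
    xg = np.linspace(smooth.x_obs.min(), smooth.x_obs.max(), grid_size)
    dcurves = smooth.derivative_curves(xg)
    lo = np.quantile(dcurves, 0.025, axis=0)
    hi = np.quantile(dcurves, 0.975, axis=0)
    sig = (lo > 0) | (hi < 0)  # derivative credibly non-zero pointwise
    if not sig.any():
        return None
    dmean = dcurves.mean(axis=0)
    # anchor at the most *credibly* steep point: boundary wiggles have wide
    # bands and small lower-bound magnitude, so they cannot steal the anchor
    lower_mag = np.where(sig, np.minimum(np.abs(lo), np.abs(hi)), 0.0)
    peak = int(np.argmax(lower_mag))
    half = np.abs(dmean[peak]) / 2.0
    mask = (np.abs(dmean) >= half) & sig
    start = peak
    while start > 0 and mask[start - 1]:
        start -= 1
    end = peak
    while end < grid_size - 1 and mask[end + 1]:
        end += 1
    if (end - start + 1) >= full_span_fraction * grid_size:
        return None
    # posterior of the onset location: per draw, walk left from the anchor
    # to where the draw's derivative magnitude drops below half its value
    # at the anchor
    mags = np.abs(dcurves)
    below = mags[:, :peak + 1] < mags[:, [peak]] / 2.0
    onsets = np.full(mags.shape[0], xg[0])
    for d in range(mags.shape[0]):
        idx = np.nonzero(below[d])[0]
        if idx.size:
            i = idx[-1]  # last sub-half point left of the anchor
            onsets[d] = 0.5 * (xg[i] + xg[min(i + 1, peak)])
    return float(np.quantile(onsets, 0.025)), float(np.quantile(onsets, 0.975))


def variance_decomposition(fit: Stage2Fit) -> dict:
    """Cross-tract variance shares of spatial field, smooths, and residual.

    Shares are the empirical across-tract variances of the posterior-mean
    spatial field, the summed posterior-mean smooth contributions, and the
    unexplained residual beta_hat - posterior-mean eta, normalised to sum
    to one. The stage-one measurement variance V is not part of the
    denominator.
    """
    phi_mean = fit.phi_draws.mean(axis=0)
    eta_mean = fit.eta_draws.mean(axis=0)
    alpha_mean = fit.alpha0_draws.mean()
    smooth_mean = eta_mean - alpha_mean - phi_mean
    resid = fit.beta_hat - eta_mean
    v = np.array([np.var(phi_mean), np.var(smooth_mean), np.var(resid)])
    total = v.sum()
    if total == 0:
        shares = np.array([0.0, 0.0, 1.0])
    else:
        shares = v / total
    return {"spatial": float(shares[0]), "smooth": float(shares[1]),
            "residual": float(shares[2])}


def adverse_probability(eta_draws: np.ndarray) -> np.ndarray:
    """Per-tract posterior probability of an adverse (negative) effect.

    ``eta_draws`` has shape (ndraws, n_tracts) with at least 100 draws; the
    result is the Monte-Carlo fraction of negative draws per tract.
    """
    eta = np.asarray(eta_draws, dtype=float)
    if eta.ndim != 2 or eta.shape[0] < 100:
        raise ValueError("need a (ndraws >= 100, n_tracts) draw matrix")
    return (eta < 0).mean(axis=0)
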