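"""Stage one: per-tract Bayesian additive model for term birth weight.

Within each census tract, birth weight is modelled as

    y_i ~ N(mu_i, sigma_c),
    mu_i = a_0c + beta_c * exposure_i + sum_j s_c(x_ij) + sum_k f_c(x_ik),

with a literature-elicited normal prior on the pollutant slope beta_c
(g per ppb), cubic B-spline smooths with random-walk penalties for the
continuous confounders, reference-coded factor effects for the categorical
ones, and inverse-gamma priors on the variances. All full conditionals are
conjugate, so the model is fit by a blocked Gibbs sampler; fits across
tracts are independent. Model comparison uses DIC and each tract's
residuals are screened for within-tract spatial autocorrelation with
Moran's I, which justifies omitting a within-tract spatial residual term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from ._splines import pspline_basis
from .diagnostics import dic, gelman_rubin
from .priors import PriorSpec
from .spatial import knn_weights, morans_i

__all__ = [
    "MCMCConfig",
    "SplineSpec",
    "Design",
    "Stage1Fit",
    "Stage1Result",
    "build_design",
    "fit_stage1_tract",
    "fit_all_tracts",
    "residual_moran_screen",
    "dic",
]

DEFAULT_CONTINUOUS = ("maternal_age", "gestation", "ndvi_500m")
DEFAULT_CATEGORICAL = ("ethnicity", "education", "parity", "care", "sex")


@dataclass
class MCMCConfig:
    """Sampler settings; defaults follow the nine-chain convention."""

    chains: int = 9
    iterations: int = 4000
    burn_in: int = 2000
    thin: int = 2
    seed: int = 0
    psrf_gate: float | None = 1.05  # None disables the convergence gate

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.psrf_gate is not None and self.chains < 2:
            raise ValueError("PSRF diagnosis requires at least 2 chains")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class SplineSpec:
    """Confounder-smooth settings: cubic B-splines, quantile knots, RW2 penalty."""

    n_knots: int = 10
    degree: int = 3
    penalty_order: int = 2
    knot_rule: str = "quantile"


@dataclass
class _Block:
    name: str
    kind: str  # intercept | pollutant | spline | factor
    sl: slice
    K: np.ndarray | None = None  # penalty, spline blocks only


@dataclass
class Design:
    """Assembled design for one tract: response, blocks, prior plumbing."""

    y: np.ndarray
    X: np.ndarray
    blocks: list
    exposure_center: float
    y_center: float
    dropped: list = field(default_factory=list)
    log_jacobian: float = 0.0  # sum log |tr'(y_i)| of the outcome transform

    @property
    def pollutant_index(self) -> int:
        for b in self.blocks:
            if b.kind == "pollutant":
                return b.sl.start
        raise ValueError("no pollutant block in design")


def _transform_outcome(y: np.ndarray, transform) -> tuple[np.ndarray, float]:
    """Apply the outcome transform; return (tr(y), sum log|tr'(y)|)."""
    if transform in (None, "identity"):
        return y, 0.0
    if transform == "log":
        if (y <= 0).any():
            raise ValueError("log transform requires positive outcomes")
        return np.log(y), float(-np.sum(np.log(y)))
    if isinstance(transform, tuple) and transform[0] == "boxcox":
        lam = float(transform[1])
        if (y <= 0).any():
            raise ValueError("box-cox transform requires positive outcomes")
        yt = np.log(y) if lam == 0 else (y**lam - 1.0) / lam
        return yt, float((lam - 1.0) * np.sum(np.log(y)))
    raise ValueError(f"unknown outcome transform {transform!r}")


def build_design(records: pd.DataFrame, spline_spec: SplineSpec | None = None,
                 pollutant_col: str = "exposure", outcome_col: str = "weight",
                 continuous=DEFAULT_CONTINUOUS, categorical=DEFAULT_CATEGORICAL,
                 transform="identity") -> Design:
    """Assemble the stage-one design matrix and penalty blocks.

    The exposure column stays in ppb (centred, which leaves the slope
    untouched and decorrelates it from the intercept); continuous
    confounders enter through column-centred B-spline bases (the fitted
    smooth then sums to zero over the observed values); categorical
    confounders are dummy-coded against their most frequent level. A
    constant continuous covariate is dropped with a warning; a
    rank-deficient factor block is an error naming the factor.
    """
    spec = spline_spec or SplineSpec()
    n = len(records)
    cols: list[np.ndarray] = [np.ones((n, 1))]
    blocks: list[_Block] = [_Block("intercept", "intercept", slice(0, 1))]
    p = 1
    x = records[pollutant_col].to_numpy(float)
    xc = float(x.mean())
    cols.append((x - xc)[:, None])
    blocks.append(_Block(pollutant_col, "pollutant", slice(p, p + 1)))
    p += 1
    dropped = []
    for name in continuous:
        if name not in records.columns:
            continue
        v = records[name].to_numpy(float)
        n_distinct = np.unique(v).size
        if n_distinct < 2:
            warnings.warn(f"constant continuous covariate {name!r} dropped from design")
            dropped.append(name)
            continue
        n_knots = min(spec.n_knots, max(1, n_distinct - spec.degree - 1))
        B, K, _ = pspline_basis(v, n_knots=n_knots, degree=spec.degree,
                                penalty_order=spec.penalty_order,
                                knot_rule=spec.knot_rule)
        B = B - B.mean(axis=0, keepdims=True)  # sum-to-zero over observations
        cols.append(B)
        blocks.append(_Block(name, "spline", slice(p, p + B.shape[1]), K=K))
        p += B.shape[1]
    for name in categorical:
        if name not in records.columns:
            continue
        v = records[name].astype("category")
        ref = v.value_counts().idxmax()
        levels = [l for l in v.cat.categories if l != ref and (v == l).any()]
        if not levels:
            dropped.append(name)
            continue
        Dm = np.column_stack([(v == l).to_numpy(float) for l in levels])
        if np.linalg.matrix_rank(Dm) < Dm.shape[1]:
            raise ValueError(f"rank-deficient factor block: {name}")
        cols.append(Dm)
        blocks.append(_Block(name, "factor", slice(p, p + Dm.shape[1])))
        p += Dm.shape[1]
    y, log_jac = _transform_outcome(records[outcome_col].to_numpy(float), transform)
    yc = float(y.mean())
    return Design(y=y - yc, X=np.hstack(cols), blocks=blocks,
                  exposure_center=xc, y_center=yc, dropped=dropped,
                  log_jacobian=log_jac)


@dataclass
class Stage1Fit:
    """Posterior summary of one tract's pollutant slope (g per ppb)."""

    tract_id: str
    beta_mean: float
    beta_sd: float
    beta_draws: np.ndarray
    dic: float
    pD: float
    dbar: float
    psrf: float
    converged: bool
    residuals: np.ndarray
    n_births: int
    moran_p: float | None = None


_IG_A = 0.001
_IG_B = 0.001
_FLAT_PREC = 1e-6  # effectively flat normal (variance 1e6) on unpenalized terms


def _gibbs_chain(design: Design, prior: PriorSpec, n_iter: int, burn: int, thin: int,
                 rng: np.random.Generator, sigma_fixed: float | None):
    """One chain of the blocked Gibbs sampler; returns thinned draws."""
    X, y = design.X, design.y
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    bi = design.pollutant_index
    prior_prec = np.full(p, _FLAT_PREC)
    prior_prec[bi] = 1.0 / prior.sd**2
    b0 = np.zeros(p)
    b0[bi] = prior.mean / prior.sd**2  # precision-weighted prior mean
    spline_blocks = [(b.sl, b.K, max(1, b.K.shape[0] - np.sum(np.abs(
        np.linalg.eigvalsh(b.K)) < 1e-9))) for b in design.blocks if b.kind == "spline"]

    theta = np.zeros(p)
    delta2 = np.ones(len(spline_blocks))
    sigma2 = float(np.var(y)) if sigma_fixed is None else sigma_fixed**2
    keep = (n_iter - burn + thin - 1) // thin
    coef_draws = np.empty((keep, p))
    sig2_draws = np.empty(keep)
    dev_draws = np.empty(keep)
    k = 0
    for it in range(n_iter):
        # joint coefficient update (conjugate normal block)
        P = np.diag(prior_prec).copy()
        for j, (sl, K, _) in enumerate(spline_blocks):
            P[sl, sl] += K / delta2[j]
        A = XtX / sigma2 + P
        b = Xty / sigma2 + b0
        c, low = cho_factor(A, lower=True)
        mean = cho_solve((c, low), b)
        z = rng.standard_normal(p)
        theta = mean + solve_triangular(c, z, lower=True, trans="T")
        # smoothing variances
        for j, (sl, K, rk) in enumerate(spline_blocks):
            quad = float(theta[sl] @ K @ theta[sl])
            delta2[j] = 1.0 / rng.gamma(_IG_A + rk / 2.0, 1.0 / (_IG_B + quad / 2.0))
        resid = y - X @ theta
        ssr = float(resid @ resid)
        if sigma_fixed is None:
            sigma2 = 1.0 / rng.gamma(_IG_A + n / 2.0, 1.0 / (_IG_B + ssr / 2.0))
        if it >= burn and (it - burn) % thin == 0:
            coef_draws[k] = theta
            sig2_draws[k] = sigma2
            # deviance on the original outcome scale (transform Jacobian
            # included so DIC is comparable across transforms)
            dev_draws[k] = (n * np.log(2.0 * np.pi * sigma2) + ssr / sigma2
                            - 2.0 * design.log_jacobian)
            k += 1
    return coef_draws[:k], sig2_draws[:k], dev_draws[:k]


def fit_stage1_tract(records_or_design, prior: PriorSpec, mcmc: MCMCConfig,
                     spline_spec: SplineSpec | None = None,
                     sigma_fixed: float | None = None,
                     tract_id: str = "", seed: int | None = None,
                     **design_kwargs) -> Stage1Fit:
    """Fit the per-tract model by blocked Gibbs sampling.

    ``prior`` must already be on the model (per-ppb) scale. ``sigma_fixed``
    holds the residual sd at a known value (used by closed-form checks).
    Chains are pooled after burn-in; the slope's PSRF above the configured
    gate marks the fit as not converged rather than failing silently.
    """
    design = (records_or_design if isinstance(records_or_design, Design)
              else build_design(records_or_design, spline_spec, **design_kwargs))
    base_seed = mcmc.seed if seed is None else seed
    coef_chains, sig2_all, dev_all = [], [], []
    for ch in range(mcmc.chains):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=base_seed,
                                                           spawn_key=(ch,)))
        coefs, sig2, dev = _gibbs_chain(design, prior, mcmc.iterations, mcmc.burn_in,
                                        mcmc.thin, rng, sigma_fixed)
        coef_chains.append(coefs)
        sig2_all.append(sig2)
        dev_all.append(dev)
    bi = design.pollutant_index
    beta_chains = np.stack([c[:, bi] for c in coef_chains])
    coefs = np.concatenate(coef_chains)
    sig2 = np.concatenate(sig2_all)
    dev = np.concatenate(dev_all)
    beta = coefs[:, bi]
    theta_bar = coefs.mean(axis=0)
    resid_bar = design.y - design.X @ theta_bar
    sig2_bar = float(sig2.mean())
    dev_at_mean = (design.y.size * np.log(2.0 * np.pi * sig2_bar) + float(
        resid_bar @ resid_bar) / sig2_bar - 2.0 * design.log_jacobian)
    dic_val, pd_val, dbar = dic(dev, dev_at_mean) if dev.size >= 100 else (
        float(dev.mean()) * 2 - dev_at_mean, float(dev.mean()) - dev_at_mean,
        float(dev.mean()))
    psrf = float(gelman_rubin(beta_chains)) if mcmc.chains >= 2 else float("nan")
    converged = bool(mcmc.psrf_gate is None or not np.isfinite(psrf)
                     or psrf <= mcmc.psrf_gate)
    if mcmc.psrf_gate is not None and np.isfinite(psrf) and psrf > mcmc.psrf_gate:
        converged = False
    return Stage1Fit(
        tract_id=tract_id, beta_mean=float(beta.mean()), beta_sd=float(beta.std(ddof=1)),
        beta_draws=beta, dic=dic_val, pD=pd_val, dbar=dbar, psrf=psrf,
        converged=converged, residuals=resid_bar, n_births=design.y.size)


@dataclass
class Stage1Result:
    """All per-tract fits plus the cross-tract summary table."""

    fits: dict
    table: pd.DataFrame
    summary: dict


def _cross_tract_summary(table: pd.DataFrame, weighted: bool = False) -> dict:
    betas = table["beta_mean"].to_numpy()
    if weighted:
        w = 1.0 / table["beta_sd"].to_numpy() ** 2
        mean = float(np.sum(w * betas) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
    else:
        mean = float(betas.mean())
        se = float(betas.std(ddof=1) / np.sqrt(betas.size))
    return {"mean_effect": mean, "ci_low": mean - 1.96 * se,
            "ci_high": mean + 1.96 * se, "se": se,
            "mean_dic": float(table["dic"].mean()), "n_tracts": int(betas.size)}


def fit_all_tracts(records: pd.DataFrame, tracts: pd.DataFrame, prior: PriorSpec,
                   mcmc: MCMCConfig, spline_spec: SplineSpec | None = None,
                   sigma_fixed: float | None = None, weighted_summary: bool = False,
                   **design_kwargs) -> Stage1Result:
    """Independent per-tract fits and a cross-tract effect summary.

    Each tract's sampler seed is derived from the MCMC seed and the tract's
    position in the tract table, so results do not depend on execution
    order. The summary is the unweighted cross-tract mean of the posterior
    slopes with a normal-approximation 95 % CI, plus the mean DIC.
    """
    fits: dict[str, Stage1Fit] = {}
    rows = []
    grouped = dict(list(records.groupby("tract_id", sort=False)))
    for t_idx, tid in enumerate(tracts["tract_id"]):
        sub = grouped.get(tid)
        if sub is None or len(sub) == 0:
            continue
        seed = int(np.random.SeedSequence(entropy=mcmc.seed,
                                          spawn_key=(1000 + t_idx,)).generate_state(1)[0]
                   % (2**31))
        fit = fit_stage1_tract(sub, prior, mcmc, spline_spec, sigma_fixed,
                               tract_id=str(tid), seed=seed, **design_kwargs)
        fits[str(tid)] = fit
        rows.append({"tract_id": str(tid), "beta_mean": fit.beta_mean,
                     "beta_sd": fit.beta_sd, "dic": fit.dic, "pD": fit.pD,
                     "psrf": fit.psrf, "converged": fit.converged,
                     "n_births": fit.n_births})
    table = pd.DataFrame(rows)
    return Stage1Result(fits=fits, table=table,
                        summary=_cross_tract_summary(table, weighted_summary))


def residual_moran_screen(fits: dict, births: pd.DataFrame, k: int = 8,
                          min_n: int = 10, alpha: float = 0.05
                          ) -> tuple[pd.DataFrame, float]:
    """Per-tract Moran's I on stage-one residuals at residential locations.

    Uses symmetrised k-nearest-neighbour weights within each tract; tracts
    with fewer than ``min_n`` residuals are skipped with a warning. Returns
    the per-tract p-values and the fraction of screened tracts without
    significant autocorrelation (p >= alpha) - the quantity that justifies
    omitting a within-tract spatial term when it is large.
    """
    rows = []
    grouped = dict(list(births.groupby("tract_id", sort=False)))
    for tid, fit in fits.items():
        sub = grouped.get(tid)
        if sub is None or len(sub) < min_n:
            warnings.warn(f"tract {tid}: fewer than {min_n} residuals, skipped")
            continue
        coords = sub[["x_km", "y_km"]].to_numpy(float)
        res = morans_i(fit.residuals, knn_weights(coords, k=min(k, len(sub) - 1)))
        rows.append({"tract_id": tid, "moran_i": res.I, "moran_p": res.p})
        fit.moran_p = res.p
    table = pd.DataFrame(rows)
    frac = float((table["moran_p"] >= alpha).mean()) if len(table) else float("nan")
    return table, frac
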