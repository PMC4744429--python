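"""Synthetic cohort generator: tract lattice, covariates, true effects, births.

Birth-registry data of the kind this pipeline analyses are restricted, so
every downstream stage is exercised on synthetic data generated here with
the statistical structure the two-stage model assumes: a square lattice of
census tracts with rook adjacency, tract covariates (optionally spatially
smoothed), a true per-tract pollutant slope composed of an overall level,
smooth covariate contributions and a proper-CAR spatial field, and
individual term births whose weight responds linearly to exposure at the
tract's true slope.

Default magnitudes follow the study population the model was designed for:
mean term birth weight 3393 g, mean NO2-like exposure 25 ppb with IQR 11.43
ppb, maternal age centred at 28.8 years, 50-500 births per tract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from shapely.geometry import box

from .spatial import SpatialWeights, car_precision, car_rho_interval, lattice_rook_weights

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_lattice",
    "simulate_tract_covariates",
    "simulate_true_effects",
    "simulate_births",
    "simulate_cohort",
    "COVARIATE_MENU",
]

_Z75 = stats.norm.ppf(0.75)  # quartile point of the standard normal


@dataclass
class SimConfig:
    """Generative settings for one synthetic cohort.

    ``alpha0_true`` is the population-average pollutant slope in g per ppb
    (-1.47 g/ppb = -14.7 g per 10 ppb); ``smooth_specs`` lists the tract
    covariates that modify the slope, each as (name, form, params) with form
    in {"linear", "threshold", "constant"}; ``rho_true``/``tau_sp`` set the
    CAR spatial field; ``sigma_y`` is the individual residual sd in grams.
    """

    grid_side: int = 15
    births_per_tract_range: tuple[int, int] = (50, 500)
    alpha0_true: float = -1.47  # g per ppb
    smooth_specs: list = field(default_factory=lambda: [
        ("pct_drive_to_work", "linear", {"slope": -3.0}),
        ("pct_heavy_industry", "threshold", {"knee": 0.18, "slope": -10.0}),
    ])
    rho_true: float = 0.9
    tau_sp: float = 0.5  # g per ppb, spatial field sd scale
    sigma_y: float = 450.0  # g, conventional term-birth-weight residual sd
    exposure_mean: float = 25.0  # ppb
    exposure_iqr: float = 11.43  # ppb
    target_mean_weight: float = 3393.0  # g
    baseline_weight: float | None = None  # derived from target if None
    gestation_effect: float = 50.0  # g per week, centred
    sex_effect: float = 60.0  # g, male minus female
    confounder_scale: float = 1.0  # 0 switches all confounder effects off
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_side < 3:
            raise ValueError("grid_side must be >= 3")
        lo, hi = self.births_per_tract_range
        if lo < 1 or hi < lo:
            raise ValueError("births_per_tract_range must satisfy 1 <= min <= max")
        if not self.sigma_y > 0:
            raise ValueError("sigma_y must be > 0")
        if self.tau_sp < 0:
            raise ValueError("tau_sp must be >= 0")

    def resolved_baseline(self) -> float:
        if self.baseline_weight is not None:
            return self.baseline_weight
        # smooths and the CAR field are centred, so E[weight] hits the target
        return self.target_mean_weight - self.alpha0_true * self.exposure_mean


@dataclass
class SimTruth:
    """True per-tract decomposition of the pollutant slope (g per ppb)."""

    alpha0: float
    beta_true: np.ndarray
    spatial_field_true: np.ndarray
    smooth_values_true: pd.DataFrame  # one column per smoothed covariate

    def __post_init__(self) -> None:
        recon = self.alpha0 + self.smooth_values_true.sum(axis=1).to_numpy() + self.spatial_field_true
        if not np.allclose(recon, self.beta_true, atol=1e-10):
            raise ValueError("SimTruth decomposition identity violated")


def simulate_lattice(grid_side: int, seed: int = 0, cell_km: float = 2.0) -> pd.DataFrame:
    """Square lattice of grid_side^2 tracts as shapely cells.

    Cells are cell_km x cell_km squares (default 4 km^2, the study region's
    mean tract area). The layout is deterministic; ``seed`` is accepted for
    interface uniformity.
    """
    if grid_side < 3:
        raise ValueError("grid_side must be >= 3")
    rows, cols = np.divmod(np.arange(grid_side**2), grid_side)
    geoms = [box(c * cell_km, r * cell_km, (c + 1) * cell_km, (r + 1) * cell_km)
             for r, c in zip(rows, cols)]
    return pd.DataFrame({
        "tract_id": [f"t{r:03d}{c:03d}" for r, c in zip(rows, cols)],
        "row": rows,
        "col": cols,
        "area_km2": cell_km**2,
        "geometry": geoms,
    })


def lattice_weights(tracts: pd.DataFrame) -> SpatialWeights:
    """Rook weights of a simulated lattice from its row/col indices."""
    return lattice_rook_weights(tracts["row"].to_numpy(), tracts["col"].to_numpy(),
                                ids=tracts["tract_id"].to_numpy())


# name -> (kind, params); percentages mapped through a probit link so the
# latent field can be spatially smoothed before transformation
COVARIATE_MENU: dict[str, tuple] = {
    "median_income": ("lognormal", {"median": 55_000.0, "sigma": 0.45}),
    "pct_hispanic": ("range", {"lo": 0.0, "hi": 1.0, "mean": 0.54, "spread": 1.0}),
    "pct_white": ("range", {"lo": 0.0, "hi": 1.0, "mean": 0.24, "spread": 1.0}),
    "pct_black": ("range", {"lo": 0.0, "hi": 0.6, "mean": 0.06, "spread": 0.8}),
    "pct_asian": ("range", {"lo": 0.0, "hi": 0.8, "mean": 0.13, "spread": 0.8}),
    "pct_low_education": ("range", {"lo": 0.0, "hi": 1.0, "mean": 0.52, "spread": 0.8}),
    "pct_drive_to_work": ("range", {"lo": 0.3, "hi": 0.98, "mean": 0.72, "spread": 0.6}),
    "pct_walk_bike": ("range", {"lo": 0.0, "hi": 0.3, "mean": 0.05, "spread": 0.6}),
    "pct_commute_lt30": ("range", {"lo": 0.2, "hi": 0.95, "mean": 0.60, "spread": 0.6}),
    "pct_gas_heating": ("range", {"lo": 0.1, "hi": 0.98, "mean": 0.60, "spread": 0.7}),
    "pct_heavy_industry": ("range", {"lo": 0.0, "hi": 0.30, "mean": 0.10, "spread": 1.0}),
    "pct_electrical_power": ("range", {"lo": 0.0, "hi": 0.12, "mean": 0.02, "spread": 1.0}),
    "pct_park": ("range", {"lo": 0.0, "hi": 0.40, "mean": 0.08, "spread": 0.9}),
    "ndvi_tract": ("range", {"lo": 0.0, "hi": 0.6, "mean": 0.26, "spread": 0.5}),
    "dist_freeway_km": ("exponential", {"scale": 2.0, "floor": 0.05}),
}


def _latent_to_value(z: np.ndarray, kind: str, params: dict) -> np.ndarray:
    if kind == "range":
        lo, hi, mean, spread = params["lo"], params["hi"], params["mean"], params["spread"]
        mu = stats.norm.ppf((mean - lo) / (hi - lo))
        return lo + (hi - lo) * stats.norm.cdf(mu + spread * z)
    if kind == "lognormal":
        return np.exp(np.log(params["median"]) + params["sigma"] * z)
    if kind == "exponential":
        return params["floor"] + stats.expon.ppf(stats.norm.cdf(z)) * params["scale"]
    raise ValueError(f"unknown covariate kind {kind!r}")


def simulate_tract_covariates(tracts: pd.DataFrame, seed: int = 0,
                              names: Sequence[str] | None = None,
                              smooth: bool = True, passes: int = 2,
                              weights: SpatialWeights | None = None) -> pd.DataFrame:
    """Attach socio-demographic / commute / land-use covariates to tracts.

    Each covariate is a transform of a standard-normal latent field; with
    ``smooth`` the latent field is neighbour-averaged ``passes`` times
    (re-standardised) so the covariate is positively spatially
    autocorrelated, as real tract covariates are.
    """
    names = list(COVARIATE_MENU) if names is None else list(names)
    for nm in names:
        if nm not in COVARIATE_MENU:
            raise ValueError(f"unknown covariate name {nm!r}")
    rng = np.random.default_rng(seed)
    out = tracts.copy()
    if smooth:
        sw = weights if weights is not None else lattice_weights(tracts)
        A = sw.W + sparse.identity(sw.n, format="csr")
        A = A.multiply(1.0 / np.asarray(A.sum(axis=1)))
    for nm in names:
        kind, params = COVARIATE_MENU[nm]
        z = rng.standard_normal(len(tracts))
        if smooth:
            for _ in range(passes):
                z = np.asarray(A @ z)
            z = (z - z.mean()) / z.std()
        out[nm] = _latent_to_value(z, kind, params)
    return out


def _smooth_contribution(x: np.ndarray, form: str, params: dict) -> np.ndarray:
    if form == "linear":
        v = params["slope"] * x
    elif form == "threshold":
        v = params["slope"] * np.maximum(x - params["knee"], 0.0)
    elif form == "constant":
        v = np.full_like(x, float(params.get("value", 0.0)))
    else:
        raise ValueError(f"unknown smooth form {form!r}")
    return v - v.mean()  # centred so alpha0 is the population-average slope


def simulate_true_effects(tracts: pd.DataFrame, weights: SpatialWeights,
                          config: SimConfig, seed: int | None = None) -> SimTruth:
    """Compose the true per-tract slope: level + smooths + proper-CAR field.

    The spatial field is drawn from N(0, tau_sp^2 (D - rho W)^{-1}) via the
    Cholesky factor of the precision; tau_sp = 0 yields an exactly zero
    field.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = len(tracts)
    smooth_vals = {}
    for name, form, params in config.smooth_specs:
        if name not in tracts.columns:
            raise ValueError(f"smooth covariate {name!r} not present in tract table")
        smooth_vals[name] = _smooth_contribution(tracts[name].to_numpy(float), form, params)
    smooth_df = pd.DataFrame(smooth_vals if smooth_vals else None, index=tracts.index)
    if config.tau_sp == 0.0:
        phi = np.zeros(n)
    else:
        lo, hi = car_rho_interval(weights)
        if not (lo < config.rho_true < hi):
            raise ValueError(
                f"rho_true={config.rho_true} outside admissible interval ({lo:.4f}, {hi:.4f})")
        Q = car_precision(weights, config.rho_true, config.tau_sp).toarray()
        L = np.linalg.cholesky(Q)
        # x = L^-T z  has covariance Q^{-1}
        from scipy.linalg import solve_triangular
        phi = solve_triangular(L.T, rng.standard_normal(n), lower=False)
    total_smooth = smooth_df.sum(axis=1).to_numpy() if len(smooth_df.columns) else np.zeros(n)
    beta = config.alpha0_true + total_smooth + phi
    return SimTruth(alpha0=config.alpha0_true, beta_true=beta,
                    spatial_field_true=phi, smooth_values_true=smooth_df)


def _lognormal_params(mean: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and inter-quartile range."""
    ratio = iqr / mean

    def f(s: float) -> float:
        return 2.0 * np.sinh(_Z75 * s) * np.exp(-0.5 * s * s) - ratio

    # IQR/mean rises then falls in sigma; take the small-sigma root
    peak = optimize.minimize_scalar(lambda s: -f(s), bounds=(1e-6, 3.0),
                                    method="bounded").x
    if f(peak) < 0:
        raise ValueError("IQR/mean ratio not attainable by a log-normal")
    s = optimize.brentq(f, 1e-6, peak)
    return float(np.log(mean) - 0.5 * s * s), float(s)


_ETHNICITY = (["hispanic", "white", "asian", "black", "other"],
              [0.54, 0.24, 0.13, 0.06, 0.03])
_EDUCATION = (["lt_9th", "9th_to_hs", "some_college", "college_plus"],
              [0.10, 0.42, 0.29, 0.19])
# centred additive offsets in grams, modest by design (simulation knobs,
# not literature estimates)
_ETHNICITY_EFFECT = {"hispanic": -20.0, "white": 30.0, "asian": -30.0,
                     "black": -40.0, "other": 0.0}
_EDUCATION_EFFECT = {"lt_9th": -30.0, "9th_to_hs": -10.0,
                     "some_college": 10.0, "college_plus": 30.0}


def simulate_births(tracts: pd.DataFrame, truth: SimTruth, config: SimConfig,
                    seed: int | None = None) -> pd.DataFrame:
    """Individual term-birth records consistent with the true tract slopes.

    weight_i = baseline + beta_true(tract) * exposure_i + centred confounder
    contributions + N(0, sigma_y). Exposures are log-normal matched to the
    configured mean/IQR; confounders follow study-population-like marginals;
    gestation is restricted to the term window (37-45 weeks). Residential
    coordinates are uniform within the tract cell.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.births_per_tract_range
    mu_e, s_e = _lognormal_params(config.exposure_mean, config.exposure_iqr)
    baseline = config.resolved_baseline()
    cs = config.confounder_scale

    frames = []
    for t_idx, trow in enumerate(tracts.itertuples(index=False)):
        n = int(rng.integers(lo, hi + 1))
        exposure = np.exp(mu_e + s_e * rng.standard_normal(n))
        age = np.clip(rng.normal(28.8, 6.0, n), 15.0, 48.0)
        gest = np.clip(np.round(rng.normal(39.6, 1.3, n)), 37, 45).astype(int)
        sex = rng.choice(["male", "female"], n, p=[0.49, 0.51])
        eth = rng.choice(_ETHNICITY[0], n, p=_ETHNICITY[1])
        edu = rng.choice(_EDUCATION[0], n, p=_EDUCATION[1])
        parity = rng.choice(["first", "second_plus"], n, p=[0.4, 0.6])
        care = rng.choice(["first_trimester", "later_or_none"], n, p=[0.85, 0.15])
        ndvi = np.clip(rng.normal(0.26, 0.07, n), -1.0, 1.0)
        minx, miny, maxx, maxy = trow.geometry.bounds
        x = rng.uniform(minx, maxx, n)
        y = rng.uniform(miny, maxy, n)

        contrib = np.zeros(n)
        if cs != 0.0:
            contrib += cs * config.sex_effect * ((sex == "male") - 0.49)
            contrib += cs * config.gestation_effect * (gest - 39.6)
            # inverted-U maternal age effect, peak near 30, amplitude ~30 g
            contrib += cs * (-30.0) * (((age - 30.0) / 10.0) ** 2 - 0.36)
            contrib += cs * np.array([_ETHNICITY_EFFECT[e] for e in eth])
            contrib -= cs * sum(p * _ETHNICITY_EFFECT[k]
                                for k, p in zip(*_ETHNICITY))
            contrib += cs * np.array([_EDUCATION_EFFECT[e] for e in edu])
            contrib -= cs * sum(p * _EDUCATION_EFFECT[k]
                                for k, p in zip(*_EDUCATION))
            contrib += cs * 30.0 * ((parity == "second_plus") - 0.6)
            contrib += cs * 40.0 * ((care == "first_trimester") - 0.85)
            contrib += cs * 30.0 * (ndvi - 0.26)

        weight = (baseline + truth.beta_true[t_idx] * exposure + contrib
                  + rng.normal(0.0, config.sigma_y, n))
        frames.append(pd.DataFrame({
            "id": [f"{trow.tract_id}_{i:05d}" for i in range(n)],
            "weight": weight,
            "gestation": gest,
            "plurality": "singleton",
            "defect_status": "none",
            "maternal_age": age,
            "ethnicity": eth,
            "education": edu,
            "parity": parity,
            "care": care,
            "sex": sex,
            "ndvi_500m": ndvi,
            "tract_id": trow.tract_id,
            "x_km": x,
            "y_km": y,
            "exposure": exposure,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_cohort(config: SimConfig, covariate_names: Sequence[str] | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, SpatialWeights, SimTruth]:
    """Full generator chain: lattice -> covariates -> truth -> births.

    Sub-seeds are derived deterministically from ``config.seed`` so the whole
    chain is reproducible. Returns (births, tracts, weights, truth).
    """
    ss = np.random.SeedSequence(config.seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    tracts = simulate_lattice(config.grid_side)
    weights = lattice_weights(tracts)
    tracts = simulate_tract_covariates(tracts, seed=sub[0], names=covariate_names,
                                       weights=weights)
    truth = simulate_true_effects(tracts, weights, config, seed=sub[1])
    births = simulate_births(tracts, truth, config, seed=sub[2])
    counts = births.groupby("tract_id").size()
    tracts = tracts.assign(n_births=counts.reindex(tracts["tract_id"]).fillna(0).astype(int).to_numpy())
    return births, tracts, weights, truth
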