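"""Cohort preparation: inclusion rules, exposure windows, tract aggregation.

The analysis cohort keeps singleton term births (37-45 completed weeks)
without recorded or unknown birth defects, and keeps census tracts that are
small enough to be homogeneous (<= 50 km^2), populous enough to fit
(>= 50 births), connected to the adjacency graph (no islands), and not
outliers on tract-mean outcome or covariates by Tukey's outer fences
(Q1 - 3 IQR, Q3 + 3 IQR). Rules are applied sequentially and every excluded
unit is tallied exactly once, so the tally is conservative:
input = output + sum of rule counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial import SpatialWeights

__all__ = [
    "ExclusionTally",
    "filter_births",
    "outer_fences",
    "filter_tracts",
    "gestation_windows",
    "window_average_exposure",
    "aggregate_tract_covariates",
    "summarise_tracts",
]

BIRTH_RULES = ("multiple", "defect", "unknown_defect_status", "non_term")
TRACT_RULES = ("large_area", "few_births", "island", "outlier")


@dataclass
class ExclusionTally:
    """Sequential exclusion accounting for one filtering pass."""

    input_count: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def removed(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def output_count(self) -> int:
        return self.input_count - self.removed

    def validate(self) -> None:
        if self.removed > self.input_count or any(c < 0 for c in self.counts.values()):
            raise ValueError("exclusion tally violates conservation")

    def to_dict(self) -> dict:
        return {"input": self.input_count, "rules": dict(self.counts),
                "removed": self.removed, "output": self.output_count}


def filter_births(records: pd.DataFrame, term_window: tuple[int, int] = (37, 45)
                  ) -> tuple[pd.DataFrame, ExclusionTally]:
    """Keep singleton, defect-free term births; tally exclusions in order.

    Order of rules: multiples, recorded defects, unknown defect status,
    non-term gestation. A record failing several rules is counted once under
    the first that applies.
    """
    required = ["weight", "gestation", "plurality", "defect_status"]
    for col in required:
        if col not in records.columns:
            raise ValueError(f"missing required field: {col}")
    tally = ExclusionTally(input_count=len(records))
    remaining = records
    rules = {
        "multiple": lambda df: df["plurality"] != "singleton",
        "defect": lambda df: df["defect_status"] == "defect",
        "unknown_defect_status": lambda df: df["defect_status"] == "unknown",
        "non_term": lambda df: ~df["gestation"].between(*term_window),
    }
    for name, flag in rules.items():
        drop = flag(remaining)
        tally.counts[name] = int(drop.sum())
        remaining = remaining[~drop]
    tally.validate()
    return remaining.reset_index(drop=True), tally


def outer_fences(values) -> tuple[float, float]:
    """Tukey outer fences (Q1 - 3 IQR, Q3 + 3 IQR), linear-interpolation quantiles."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("need at least 4 finite values for outer fences")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # default 'linear' convention
    iqr = q3 - q1
    return float(q1 - 3.0 * iqr), float(q3 + 3.0 * iqr)


def filter_tracts(tracts: pd.DataFrame, weights: SpatialWeights,
                  covariate_cols: list[str] | None = None,
                  outcome_col: str | None = "mean_weight",
                  max_area_km2: float = 50.0, min_births: int = 50,
                  fence_multiplier: float = 3.0,
                  island_before_area: bool = False,
                  ) -> tuple[pd.DataFrame, SpatialWeights, ExclusionTally]:
    """Sequential tract exclusions with adjacency re-derived on the kept set.

    Rules in order: area above ``max_area_km2``; fewer than ``min_births``
    births; islands, i.e. tracts with no neighbour *among the tracts still
    retained at that point* (earlier removals can create new islands); outer
    -fence outliers on the tract-mean outcome and every screened covariate
    (union of flags). ``island_before_area`` swaps the island rule to the
    front for sensitivity runs.
    """
    if list(weights.ids) != list(tracts["tract_id"]):
        raise ValueError("weights ids must align with tract table order")
    if covariate_cols is None:
        from .simulate import COVARIATE_MENU
        covariate_cols = [c for c in COVARIATE_MENU if c in tracts.columns]
    tally = ExclusionTally(input_count=len(tracts))
    keep = np.ones(len(tracts), dtype=bool)

    def island_rule() -> int:
        sub = weights.W[np.ix_(keep.nonzero()[0], keep.nonzero()[0])]
        deg = np.asarray(sub.sum(axis=1)).ravel()
        drop_local = deg == 0
        n = int(drop_local.sum())
        idx = keep.nonzero()[0][drop_local]
        keep[idx] = False
        return n

    def area_rule() -> int:
        drop = keep & (tracts["area_km2"].to_numpy() > max_area_km2)
        keep[drop] = False
        return int(drop.sum())

    def births_rule() -> int:
        drop = keep & (tracts["n_births"].to_numpy() < min_births)
        keep[drop] = False
        return int(drop.sum())

    def outlier_rule() -> int:
        cols = list(covariate_cols)
        if outcome_col is not None and outcome_col in tracts.columns:
            cols = [outcome_col] + cols
        drop = np.zeros(len(tracts), dtype=bool)
        for col in cols:
            vals = tracts[col].to_numpy(float)
            v = vals[keep]
            v = v[np.isfinite(v)]
            if v.size < 4:
                continue
            q1, q3 = np.quantile(v, [0.25, 0.75])
            iqr = q3 - q1
            lo, hi = q1 - fence_multiplier * iqr, q3 + fence_multiplier * iqr
            drop |= keep & ((vals < lo) | (vals > hi))
        keep[drop] = False
        return int(drop.sum())

    order = (["island", "large_area", "few_births", "outlier"] if island_before_area
             else ["large_area", "few_births", "island", "outlier"])
    impl = {"large_area": area_rule, "few_births": births_rule,
            "island": island_rule, "outlier": outlier_rule}
    for name in order:
        tally.counts[name] = impl[name]()
    tally.validate()
    kept = tracts[keep].reset_index(drop=True)
    return kept, weights.subset(keep), tally


def gestation_windows(gestation_weeks: int, t1_end: int = 13, t2_end: int = 26
                      ) -> dict[str, tuple[int, int]]:
    """Trimester and full-pregnancy windows in gestation weeks (inclusive).

    Boundaries default to the common obstetric convention: weeks 1-13,
    14-26, 27-delivery.
    """
    if gestation_weeks <= t2_end:
        raise ValueError("gestation shorter than the trimester boundaries")
    return {"t1": (1, t1_end), "t2": (t1_end + 1, t2_end),
            "t3": (t2_end + 1, gestation_weeks), "full": (1, gestation_weeks)}


def window_average_exposure(weekly, windows: dict[str, tuple[int, int]]
                            ) -> dict[str, float]:
    """Arithmetic mean of a weekly exposure series over each window.

    ``weekly[i]`` is gestation week i+1; windows are inclusive (start, end)
    week ranges that must lie within the series.
    """
    w = np.asarray(weekly, dtype=float)
    out = {}
    for name, (start, end) in windows.items():
        if start < 1 or end > w.size or end < start:
            raise ValueError(f"window {name!r} ({start}, {end}) empty or outside the series")
        out[name] = float(w[start - 1:end].mean())
    return out


def aggregate_tract_covariates(block_values, block_areas, block_to_tract) -> pd.Series:
    """Area-weighted aggregation of block-level values to tracts."""
    df = pd.DataFrame({
        "value": np.asarray(block_values, dtype=float),
        "area": np.asarray(block_areas, dtype=float),
        "tract": np.asarray(block_to_tract),
    })
    if (df["area"] <= 0).any():
        raise ValueError("block areas must be > 0")
    grouped = df.groupby("tract", sort=False)
    num = grouped.apply(lambda g: float((g["value"] * g["area"]).sum()), include_groups=False)
    den = grouped["area"].sum()
    if (den <= 0).any():
        raise ValueError("tract with zero total area")
    return num / den


def summarise_tracts(births: pd.DataFrame, tracts: pd.DataFrame) -> pd.DataFrame:
    """Attach per-tract birth counts and mean outcome/exposure summaries."""
    g = births.groupby("tract_id")
    summary = pd.DataFrame({
        "n_births": g.size(),
        "mean_weight": g["weight"].mean(),
        "mean_exposure": g["exposure"].mean(),
        "mean_maternal_age": g["maternal_age"].mean(),
    })
    out = tracts.drop(columns=[c for c in summary.columns if c in tracts.columns])
    return out.join(summary, on="tract_id")
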