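"""Prior elicitation for the pollutant slope from literature effect sizes.

The stage-one model places a normal prior on the per-tract pollutant slope.
For a pollutant with a substantial literature (NO2) the prior is elicited by
sample-size weighting of published effect estimates, each reported in grams
of term birth weight per 10 ppb increment. For a pollutant with sparse or
conflicting evidence (NOx) a weakly informative zero-centred normal is used
instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "LiteratureStudy",
    "PriorSpec",
    "weighted_normal_prior",
    "noninformative_prior",
    "prior_to_model_scale",
    "read_literature_csv",
]


@dataclass(frozen=True)
class LiteratureStudy:
    """One published effect estimate: grams per 10 ppb, with its sample size."""

    study_id: str
    effect: float  # g per 10 ppb, signed (negative = weight reduction)
    n: int  # study sample size, used as the pooling weight

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"study {self.study_id!r}: sample size must be >= 1")
        if not math.isfinite(self.effect):
            raise ValueError(f"study {self.study_id!r}: effect must be finite")


@dataclass(frozen=True)
class PriorSpec:
    """Normal prior for a pollutant slope.

    ``family`` is ``"normal"`` for an evidence-based prior and
    ``"weak_normal"`` for the zero-mean weakly informative one. ``scale_note``
    records the reporting scale the mean/sd are currently on.
    """

    family: str
    mean: float
    sd: float
    scale_note: str = "g per 10 ppb"

    def __post_init__(self) -> None:
        if self.family not in ("normal", "weak_normal"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if not self.sd > 0:
            raise ValueError("prior sd must be > 0")
        if self.family == "weak_normal" and self.mean != 0:
            raise ValueError("weak_normal prior must have mean 0")


def weighted_normal_prior(studies: Sequence[LiteratureStudy]) -> PriorSpec:
    """Elicit a normal prior by sample-size weighting of literature effects.

    The prior mean is the n-weighted average of the study effects and the
    prior sd the n-weighted (population-convention) standard deviation, so
    heterogeneous literatures yield diffuse priors and consistent ones yield
    concentrated priors.

    Raises
    ------
    ValueError
        With "insufficient evidence" for fewer than two studies, or
        "degenerate prior" when every effect is identical (zero weighted
        variance cannot define a proper normal).
    """
    studies = list(studies)
    if len(studies) < 2:
        raise ValueError("insufficient evidence: need at least 2 studies")
    wsum = float(sum(s.n for s in studies))
    mean = sum(s.n * s.effect for s in studies) / wsum
    var = sum(s.n * (s.effect - mean) ** 2 for s in studies) / wsum
    if var <= 0.0:
        raise ValueError("degenerate prior: zero weighted variance across studies")
    return PriorSpec(family="normal", mean=mean, sd=math.sqrt(var))


def noninformative_prior(sd: float = 1.0, scale_note: str = "g per ppb") -> PriorSpec:
    """Weakly informative Normal(0, sd) prior for a pollutant with mixed evidence.

    Default sd of 1 on the per-ppb scale; pass ``scale_note="g per 10 ppb"``
    (and rescale downstream) to place the same spread on the per-10-ppb scale.
    """
    return PriorSpec(family="weak_normal", mean=0.0, sd=sd, scale_note=scale_note)


def prior_to_model_scale(prior: PriorSpec, per_unit: float = 10.0) -> PriorSpec:
    """Convert a prior between reporting scales by dividing mean and sd.

    A prior stated per 10 ppb becomes per ppb with ``per_unit=10``; the
    operation is its own inverse with factor ``1/per_unit``.
    """
    if not per_unit > 0:
        raise ValueError("per_unit scale factor must be > 0")
    note = f"{prior.scale_note} / {per_unit:g}"
    return replace(prior, mean=prior.mean / per_unit, sd=prior.sd / per_unit, scale_note=note)


def read_literature_csv(path) -> list[LiteratureStudy]:
    """Read a literature table (study_id, effect_g_per_10ppb, n, include).

    Rows with ``include`` false are dropped; de-duplication of overlapping
    meta-analyses is the table author's responsibility via that column.
    """
    df = pd.read_csv(path)
    required = {"study_id", "effect_g_per_10ppb", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"literature table missing columns: {sorted(missing)}")
    if "include" in df.columns:
        df = df[df["include"].astype(bool)]
    return [
        LiteratureStudy(str(r.study_id), float(r.effect_g_per_10ppb), int(r.n))
        for r in df.itertuples(index=False)
    ]
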