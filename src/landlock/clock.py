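"""The waterfall clock: genetic distance vs waterfall height, erosion rate,
and per-waterfall isolation ages.

A waterfall of height ``h`` grows by differential bedrock erosion at a
(assumed constant) vertical rate ``E`` (m/yr), so the population it landlocked
has been isolated for ``t = h / E`` years.  Isolation time leaves a molecular
signature: the genetic distance ``D`` between a landlocked population and its
amphidromous source grows at the substitution rate ``R`` (per year, on the
pairwise-divergence scale), so across waterfalls

    D = intercept + C * h,     with C = R / E,

and a simple linear regression of ``D`` on ``h`` calibrates the clock:
``E = R / C`` and ``age_i = h_i / E``.  The intercept absorbs the standing
diversity of the source population (a lineage picked from the source pool is
already some distance from another source lineage at the moment of
isolation).

Populations known to descend from downstream drift rather than in-situ
isolation (e.g. a site lying between two waterfalls) must be flagged and are
excluded before fitting — that identification is biological reasoning, not an
algorithm, so it is an explicit input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .morphology import RegressionResult, simple_regression

PLAUSIBLE_EROSION_BAND_MM_YR = (0.3, 1.0)


def rate_from_percent_per_myr(percent_per_myr: float) -> float:
    """Convert a divergence rate printed as %/Myr to substitutions/site/year."""
    return percent_per_myr / 100.0 / 1e6


def load_waterfalls() -> pd.DataFrame:
    """The packaged waterfall table: name, river, steps, height (m).

    ``age_printed_yr`` carries the study's published age estimates for the
    dated falls (one fall isolates no sampled population and has none).
    """
    with resources.files("landlock.data").joinpath("waterfalls.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class ClockFit:
    """A calibrated waterfall clock.

    ``points`` holds the (name, height, distance) data actually fitted,
    after exclusions.  ``E`` is in m/yr (``E_mm_yr`` in mm/yr); ages in years.
    Invariants: ``E = R / C`` and ``age_i = h_i / E`` exactly.
    """

    points: pd.DataFrame = field(repr=False)
    regression: RegressionResult
    R: float  # substitutions/site/year
    E: float  # m/yr
    ages: pd.Series  # years, indexed by waterfall name
    excluded: tuple[str, ...] = ()

    @property
    def C(self) -> float:
        return self.regression.slope

    @property
    def E_mm_yr(self) -> float:
        return self.E * 1000.0

    def to_dict(self) -> dict:
        return {
            "slope_C_per_m": self.C,
            "intercept": self.regression.intercept,
            "F": self.regression.F,
            "df": list(self.regression.df),
            "r_squared": self.regression.r_squared,
            "p": self.regression.p,
            "R_per_year": self.R,
            "E_m_per_year": self.E,
            "E_mm_per_year": self.E_mm_yr,
            "ages_yr": {k: float(v) for k, v in self.ages.items()},
            "excluded": list(self.excluded),
        }


def fit_height_distance(points: pd.DataFrame, exclude=()) -> RegressionResult:
    """OLS of genetic distance on waterfall height.

    ``points`` needs columns ``name``, ``height_m``, ``distance``; rows whose
    name is in ``exclude`` (downstream-drift descendants) are dropped first.
    At least 3 points must remain and heights must vary and be positive.
    """
    pts = points[~points["name"].isin(set(exclude))]
    if len(pts) < 3:
        raise ValueError("need at least 3 points after exclusions")
    if (pts["height_m"] <= 0).any():
        raise ValueError("heights must be positive")
    return simple_regression(pts["height_m"], pts["distance"])


def erosion_rate(C: float, R: float) -> float:
    """E = R / C in m/yr (C: distance per m of height; R: distance per year)."""
    if not C > 0:
        raise ValueError("slope C must be positive to calibrate an erosion rate")
    if not R > 0:
        raise ValueError("substitution rate R must be positive")
    return R / C


def waterfall_ages(heights: pd.Series, E: float) -> pd.Series:
    """Ages ``h / E`` in years; waterfalls with missing height are skipped."""
    if not E > 0:
        raise ValueError("erosion rate must be positive")
    h = pd.Series(heights, dtype=float).dropna()
    if (h <= 0).any():
        raise ValueError("heights must be positive")
    return h / E


def sanity_check_erosion(E_m_yr: float) -> dict:
    """Compare E against the independent geomorphological band 0.3–1.0 mm/yr.

    Island-scale relief (elevation SD ~ 114 m) puts the expected bedrock
    erosion rate in that band; a calibrated rate outside it is flagged.
    """
    lo, hi = PLAUSIBLE_EROSION_BAND_MM_YR
    e_mm = E_m_yr * 1000.0
    status = "within" if lo <= e_mm <= hi else ("below" if e_mm < lo else "above")
    return {"E_mm_per_year": e_mm, "band_mm_per_year": [lo, hi], "status": status}


def calibrate_clock(
    points: pd.DataFrame,
    rate_percent_per_myr: float = 3.8,
    exclude=(),
    heights: pd.Series | None = None,
) -> ClockFit:
    """Full clock chain: regression, erosion rate, per-waterfall ages.

    ``heights`` defaults to the fitted points' own heights; pass the full
    waterfall table's heights (name-indexed) to also date falls that carry no
    regression point.
    """
    reg = fit_height_distance(points, exclude=exclude)
    R = rate_from_percent_per_myr(rate_percent_per_myr)
    E = erosion_rate(reg.slope, R)
    kept = points[~points["name"].isin(set(exclude))]
    if heights is None:
        heights = kept.set_index("name")["height_m"]
    return ClockFit(
        points=kept.reset_index(drop=True),
        regression=reg,
        R=R,
        E=E,
        ages=waterfall_ages(heights, E),
        excluded=tuple(exclude),
    )
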