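"""Burned-area calibration against permit records, and burn summaries.

Satellite fire products over-report burned area for the fires they detect;
state permit records are treated as the accurate area source where they
exist.  Calibration regresses gridded daily permit area on gridded daily
satellite area — pairs keyed by (cell, date), through the origin by default
— and the fitted slope is the single region-wide scaling factor applied to
every satellite area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, InputError
from .grid import GridDefinition
from .records import validate_events
from .seasons import DEFAULT_SEASONS, SeasonDefinition

__all__ = [
    "CalibrationModel",
    "match_pairs",
    "fit_scaling",
    "apply_calibration",
    "burn_summary",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Linear calibration of satellite burned area to permit burned area.

    ``slope`` is the dimensionless scaling factor (permit per satellite
    acre); ``intercept`` is zero for the default through-origin fit.
    ``r_squared`` is the squared Pearson correlation of the paired areas
    and ``residual_sd`` the standard deviation of the fit residuals in
    acres.
    """

    slope: float
    intercept: float
    n_pairs: int
    r_squared: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ConfigurationError("calibration slope must be positive")
        if self.n_pairs < 2:
            raise ConfigurationError("calibration needs at least 2 pairs")

    def as_dict(self) -> dict[str, float]:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "n_pairs": self.n_pairs,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
        }


def match_pairs(
    satellite: pd.DataFrame,
    permits: pd.DataFrame,
    grid: GridDefinition,
) -> pd.DataFrame:
    """Gridded daily matched area pairs.

    Areas are summed within each (cell, date) key; a pair is emitted for
    every key with positive satellite area, with permit total zero when no
    permit covers that key.  Keys with permits but no satellite detection
    are not paired (the satellite record is what gets calibrated);
    discarding satellite keys without permits, by contrast, would bias the
    slope upward, so they are retained.
    """
    validate_events(satellite, grid)
    validate_events(permits, grid)
    key = ["row", "col", "date"]
    sat = satellite.groupby(key)["area_acres"].sum().rename("satellite_area")
    merged = sat.to_frame()
    if len(permits):
        per = permits.groupby(key)["area_acres"].sum().rename("permit_area")
        merged = merged.join(per, how="left").fillna({"permit_area": 0.0})
    else:
        merged["permit_area"] = 0.0
    merged = merged[merged["satellite_area"] > 0]
    return merged.reset_index()[key + ["satellite_area", "permit_area"]]


def fit_scaling(pairs: pd.DataFrame, fit_intercept: bool = False) -> CalibrationModel:
    """Least-squares fit of permit area on satellite area.

    Through the origin by default: the calibration is a single scaling
    factor.  ``fit_intercept=True`` adds a free intercept instead.
    """
    s = np.asarray(pairs["satellite_area"], dtype=float)
    p = np.asarray(pairs["permit_area"], dtype=float)
    if len(s) < 2:
        raise DegenerateInputError("need at least 2 matched pairs to fit")
    if not np.any(s > 0):
        raise DegenerateInputError("all satellite areas are zero")

    if fit_intercept:
        coeffs = np.polynomial.polynomial.polyfit(s, p, 1)
        intercept, slope = float(coeffs[0]), float(coeffs[1])
    else:
        slope = float(np.dot(s, p) / np.dot(s, s))
        intercept = 0.0

    residuals = p - (intercept + slope * s)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(s, p)[0, 1]
    r2 = float(corr**2) if np.isfinite(corr) else 0.0
    return CalibrationModel(
        slope=slope,
        intercept=intercept,
        n_pairs=int(len(s)),
        r_squared=r2,
        residual_sd=float(np.std(residuals, ddof=1)),
    )


def apply_calibration(satellite: pd.DataFrame, model: CalibrationModel) -> pd.DataFrame:
    """Scale every satellite event area by the calibration slope.

    Event count, ordering and all other fields are unchanged; the
    intercept, if fitted, applies at the gridded-total level and is not
    distributed over individual events.
    """
    validate_events(satellite)
    out = satellite.copy()
    out["area_acres"] = out["area_acres"] * model.slope
    return out


def burn_summary(
    events: pd.DataFrame,
    seasons: SeasonDefinition = DEFAULT_SEASONS,
) -> pd.DataFrame:
    """Burned-area totals by year, season and ownership.

    Returns a tidy table with one row per (year, season, ownership) plus
    marginal rows where the stratifier is "all"; each row carries the
    total acres and its share of the grand total.
    """
    validate_events(events)
    if len(events) == 0:
        raise DegenerateInputError("no events to summarize")
    idx = pd.DatetimeIndex(events["date"])
    frame = pd.DataFrame(
        {
            "year": idx.year.astype(str),
            "season": seasons.of_dates(idx),
            "ownership": events["ownership"].to_numpy(),
            "area_acres": events["area_acres"].to_numpy(),
        }
    )
    grand = frame["area_acres"].sum()

    def rows(by: list[str]):
        grouped = frame.groupby(by)["area_acres"].sum().reset_index()
        for col in ("year", "season", "ownership"):
            if col not in grouped:
                grouped[col] = "all"
        return grouped

    grand_row = pd.DataFrame(
        [{"year": "all", "season": "all", "ownership": "all", "area_acres": grand}]
    )
    out = pd.concat(
        [
            rows(["year", "season", "ownership"]),
            rows(["year"]),
            rows(["season"]),
            rows(["ownership"]),
            grand_row,
        ],
        ignore_index=True,
    )[["year", "season", "ownership", "area_acres"]]
    out["share"] = out["area_acres"] / grand
    return out
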