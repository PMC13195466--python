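"""Zonal aggregation and summary statistics.

Daily regional means are area-weighted over the grid cells a region
polygon covers, with weights equal to the exact polygon-cell intersection
fraction (planar geometry in grid km coordinates).  Seasonal and annual
summaries average the daily means within each stratum; exceedance
statistics count grid-cell-days and regional-mean days at or above a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .errors import ConfigurationError, DegenerateInputError, InputError
from .grid import GridDefinition
from .seasons import DEFAULT_SEASONS, SeasonDefinition

__all__ = [
    "ZonalWeights",
    "compute_coverage_weights",
    "weighted_daily_mean",
    "period_summary",
    "pf_share",
    "exceedance_stats",
    "ExceedanceStats",
]


@dataclass(frozen=True)
class ZonalWeights:
    """Coverage weights of one region over grid cells.

    ``rows``/``cols``/``fractions`` are parallel arrays; each fraction is
    the share of that cell's area covered by the region, in (0, 1].
    """

    region: str
    rows: np.ndarray
    cols: np.ndarray
    fractions: np.ndarray
    cell_area_km2: float

    @property
    def area_km2(self) -> float:
        """Region area implied by the weights."""
        return float(self.fractions.sum() * self.cell_area_km2)


def compute_coverage_weights(grid: GridDefinition, polygon: BaseGeometry,
                             region: str = "region") -> ZonalWeights:
    """Exact polygon-cell coverage fractions by rectangle clipping.

    Only cells inside the polygon's bounding box are tested; each
    intersected cell contributes intersection area / cell area.
    """
    if polygon.is_empty or polygon.area == 0:
        raise DegenerateInputError("region polygon is empty")
    x0, y0 = grid.origin
    size = grid.cell_size_km
    minx, miny, maxx, maxy = polygon.bounds
    c_lo = max(int(np.floor((minx - x0) / size)), 0)
    c_hi = min(int(np.ceil((maxx - x0) / size)), grid.n_cols)
    r_lo = max(int(np.floor((miny - y0) / size)), 0)
    r_hi = min(int(np.ceil((maxy - y0) / size)), grid.n_rows)

    rows, cols, fracs = [], [], []
    for r in range(r_lo, r_hi):
        for c in range(c_lo, c_hi):
            cell = box(x0 + c * size, y0 + r * size, x0 + (c + 1) * size, y0 + (r + 1) * size)
            inter = polygon.intersection(cell).area
            if inter > 0:
                rows.append(r)
                cols.append(c)
                fracs.append(inter / grid.cell_area_km2)
    if not rows:
        raise DegenerateInputError("region polygon does not intersect the grid")
    return ZonalWeights(
        region=region,
        rows=np.asarray(rows),
        cols=np.asarray(cols),
        fractions=np.asarray(fracs),
        cell_area_km2=grid.cell_area_km2,
    )


def weighted_daily_mean(field: xr.DataArray, weights: ZonalWeights) -> pd.Series:
    """Area-weighted daily spatial mean of a field over one region (ug/m3)."""
    if weights.rows.max() >= field.sizes["row"] or weights.cols.max() >= field.sizes["col"]:
        raise InputError("zonal weights fall outside the field grid")
    values = field.values[:, weights.rows, weights.cols]  # (time, n_cells)
    w = weights.fractions * weights.cell_area_km2
    daily = values @ w / w.sum()
    return pd.Series(daily, index=pd.DatetimeIndex(field["time"].values), name=weights.region)


def period_summary(
    daily: pd.Series,
    seasons: SeasonDefinition = DEFAULT_SEASONS,
    clamp_negative: bool = False,
) -> pd.DataFrame:
    """Mean, sample SD and median of daily means per (year, season) and overall.

    Rows cover every year x season stratum in the series' span plus
    per-season pooled rows (year = "all") and a grand "all"/"all" row.
    Multi-year seasonal summaries pool daily means across years rather
    than averaging yearly summaries.  Strata with no days carry NaN.
    ``clamp_negative`` floors the daily series at zero first (for
    attribution deltas that may dip negative).
    """
    s = daily.copy()
    if clamp_negative:
        s = s.clip(lower=0.0)
    idx = pd.DatetimeIndex(s.index)
    frame = pd.DataFrame(
        {"value": s.to_numpy(), "year": idx.year, "season": seasons.of_dates(idx)}
    )

    def summarize(group: pd.DataFrame) -> pd.Series:
        v = group["value"]
        return pd.Series(
            {
                "n_days": len(v),
                "mean": v.mean() if len(v) else np.nan,
                "sd": v.std(ddof=1) if len(v) > 1 else (0.0 if len(v) == 1 else np.nan),
                "median": v.median() if len(v) else np.nan,
            }
        )

    out = []
    for (year, season), grp in frame.groupby(["year", "season"]):
        out.append({"year": str(year), "season": season, **summarize(grp)})
    for season, grp in frame.groupby("season"):
        out.append({"year": "all", "season": season, **summarize(grp)})
    out.append({"year": "all", "season": "all", **summarize(frame)})
    result = pd.DataFrame(out)
    result["n_days"] = result["n_days"].astype(int)
    return result


def pf_share(pf_daily: pd.Series, ambient_daily: pd.Series) -> tuple[pd.Series, float]:
    """Source share of the ambient level: daily percentages and the period
    percentage (ratio of period means, not mean of daily ratios)."""
    if not pf_daily.index.equals(ambient_daily.index):
        raise InputError("pf and ambient daily series are not aligned")
    if ambient_daily.mean() <= 0:
        raise DegenerateInputError("ambient period mean is zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        daily_pct = 100.0 * pf_daily / ambient_daily
    period_pct = float(100.0 * pf_daily.mean() / ambient_daily.mean())
    return daily_pct, period_pct


@dataclass(frozen=True)
class ExceedanceStats:
    """Threshold exceedance summary for one field and one region."""

    threshold: float
    cell_day_fraction: float
    n_cell_days: int
    n_exceeding_cell_days: int
    n_region_days: int


def exceedance_stats(
    field: xr.DataArray,
    threshold: float,
    regional_daily: pd.Series | None = None,
) -> ExceedanceStats:
    """Fraction of grid-cell-days at/above ``threshold``, and (if a regional
    daily-mean series is supplied) the count of days whose regional mean is
    at/above it."""
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    values = field.values
    n_total = values.size
    n_exc = int((values >= threshold).sum())
    n_days = (
        int((regional_daily.to_numpy() >= threshold).sum())
        if regional_daily is not None
        else 0
    )
    return ExceedanceStats(
        threshold=threshold,
        cell_day_fraction=n_exc / n_total,
        n_cell_days=n_total,
        n_exceeding_cell_days=n_exc,
        n_region_days=n_days,
    )
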