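"""Observation-model data fusion.

The fusion blends simulated concentration fields with monitor observations
so the result tracks observations where monitors exist and the model's
spatial structure elsewhere.  It has three layers:

Total PM2.5 (``fuse_total``)
    Per day, a polynomial regression maps simulated onto observed values
    over collocated pairs (a pooled climatological fit backs up sparse
    days); the corrected field is then multiplied by an inverse-distance-
    weighted interpolation of the log residual ratios observed/corrected at
    the monitors, tapering to ratio 1 beyond a cutoff radius, and floored.

Species (``fuse_species_ratios``)
    Fusion acts on species-to-total *ratios*, not absolute concentrations:
    observed ratios at speciation monitors correct the simulated ratio
    field (log-corrections interpolated linearly in time across each site's
    1-in-3-day schedule and by IDW in space), the corrected ratio vector
    {EC, OC, NO3, SO4, OTHER} is renormalized to sum to one, and fused
    species concentrations are ratio x fused total.  This preserves the
    mass balance exactly: fused components always sum to the fused total.

Prescribed-fire impacts (``fuse_pf_total`` / ``fuse_pf_species``)
    The observation-adjusted impact scales the simulated impact by the
    fused/simulated concentration ratio,

        delta_DF = delta_sim x fused / max(sim, denom_floor),

    with the multiplier capped, so the simulated source *fraction* is
    preserved wherever the cap and floor are inactive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ConfigurationError, DegenerateInputError, InputError
from .fields import SPECIES, TOTAL, check_aligned, make_field
from .grid import GridDefinition
from .records import validate_observations, validate_sites

__all__ = [
    "FusionConfig",
    "exclude_near_road",
    "fuse_total",
    "fuse_pf_total",
    "fuse_species_ratios",
    "fuse_pf_species",
    "run_fusion",
]


@dataclass(frozen=True)
class FusionConfig:
    """Tunable parameters of the fusion scheme.

    ``polynomial_degree``    degree of the daily simulated->observed fit;
    ``min_pairs_per_day``    below this, the pooled fit is used instead;
    ``idw_power``            inverse-distance exponent for residual ratios;
    ``idw_radius_km``        beyond this range the correction tapers to 1;
    ``denom_floor``          ug/m3 floor applied to every ratio denominator;
    ``ratio_cap``            cap on multiplicative corrections (and their
                             reciprocals), preventing unbounded inflation
                             where simulated values are near zero;
    ``concentration_floor``  ug/m3 floor on fused concentration fields.
    """

    polynomial_degree: int = 2
    min_pairs_per_day: int = 5
    idw_power: float = 2.0
    idw_radius_km: float = 300.0
    denom_floor: float = 0.01
    ratio_cap: float = 10.0
    concentration_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.polynomial_degree < 1:
            raise ConfigurationError("polynomial_degree must be >= 1")
        if self.denom_floor <= 0:
            raise ConfigurationError("denom_floor must be positive")
        if self.ratio_cap <= 1:
            raise ConfigurationError("ratio_cap must exceed 1")
        if self.idw_power <= 0 or self.idw_radius_km <= 0:
            raise ConfigurationError("IDW parameters must be positive")


# ---------------------------------------------------------------------------
# observation plumbing
# ---------------------------------------------------------------------------


def exclude_near_road(observations: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Drop observations from near-road monitors.

    Near-road monitors sample local traffic plumes unrepresentative of the
    12 km cell they sit in and would bias the fusion high.
    """
    validate_observations(observations)
    validate_sites(sites)
    unknown = set(observations["site"]) - set(sites["id"])
    if unknown:
        raise InputError(f"observations from unknown sites {sorted(unknown)[:5]}")
    near = set(sites.loc[sites["near_road"], "id"])
    return observations[~observations["site"].isin(near)].reset_index(drop=True)


def _collocate(
    observations: pd.DataFrame,
    sites: pd.DataFrame,
    field: xr.DataArray,
    species: str,
) -> pd.DataFrame:
    """Observations of one species joined with site cells, day indices and
    the simulated value at the observation's cell-day."""
    obs = observations[observations["species"] == species]
    merged = obs.merge(
        sites[["id", "row", "col"]], left_on="site", right_on="id", how="left"
    )
    if merged["row"].isna().any():
        raise InputError("observation from a site missing in the site table")
    dates = pd.DatetimeIndex(field["time"].values)
    pos = pd.Series(np.arange(len(dates)), index=dates)
    if not merged["date"].isin(pos.index).all():
        raise InputError("simulated field does not cover all observation dates")
    merged = merged.assign(day=pos.loc[merged["date"]].to_numpy())
    merged = merged.assign(
        sim=field.values[
            merged["day"].to_numpy(),
            merged["row"].to_numpy(dtype=int),
            merged["col"].to_numpy(dtype=int),
        ]
    )
    return merged[["site", "date", "day", "row", "col", "value", "sim"]]


# ---------------------------------------------------------------------------
# polynomial correction
# ---------------------------------------------------------------------------


class _PolyCorrection:
    """Polynomial map sim -> obs, linearly extended outside the fit range.

    Extending linearly (with slope floored at zero) avoids the wild
    extrapolation a quadratic would produce on plume cells far above any
    value seen at the monitors.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, degree: int):
        degree = min(degree, len(np.unique(x)) - 1)
        if degree < 1:
            # All simulated values identical: fall back to a ratio scaling.
            scale = float(np.sum(y) / max(np.sum(x), 1e-12))
            self._poly = np.polynomial.Polynomial([0.0, scale])
        else:
            self._poly = np.polynomial.Polynomial.fit(x, y, degree).convert()
        self._xmin = float(np.min(x))
        self._xmax = float(np.max(x))
        d = self._poly.deriv()
        self._slope_lo = max(float(d(self._xmin)), 0.0)
        self._slope_hi = max(float(d(self._xmax)), 0.0)

    def __call__(self, values: np.ndarray) -> np.ndarray:
        clipped = np.clip(values, self._xmin, self._xmax)
        out = self._poly(clipped)
        out = np.where(
            values > self._xmax, out + self._slope_hi * (values - self._xmax), out
        )
        out = np.where(
            values < self._xmin, out + self._slope_lo * (values - self._xmin), out
        )
        return out


# ---------------------------------------------------------------------------
# inverse-distance interpolation of log corrections
# ---------------------------------------------------------------------------


class _IDWInterpolator:
    """IDW of site log-corrections over the grid with a taper to zero.

    Weight of site i at a cell: ``max(0, 1 - d_i/R) / max(d_i, eps)^p``.
    At a monitor's own cell the weight diverges, so the interpolated
    correction reproduces the site value; beyond the radius all weights
    vanish and the correction is zero (ratio one).
    """

    def __init__(self, grid: GridDefinition, rows: np.ndarray, cols: np.ndarray,
                 power: float, radius_km: float):
        xx, yy = grid.cell_centers_km()
        sx = grid.origin[0] + (np.asarray(cols) + 0.5) * grid.cell_size_km
        sy = grid.origin[1] + (np.asarray(rows) + 0.5) * grid.cell_size_km
        d = np.sqrt(
            (xx.ravel()[None, :] - sx[:, None]) ** 2
            + (yy.ravel()[None, :] - sy[:, None]) ** 2
        )
        taper = np.clip(1.0 - d / radius_km, 0.0, None)
        self._w = taper / np.maximum(d, 1e-6) ** power  # (n_sites, n_cells)
        self._shape = grid.shape

    def interpolate(self, site_idx: np.ndarray, values: np.ndarray) -> np.ndarray:
        """Weighted mean of ``values`` (per listed site) at every cell."""
        w = self._w[site_idx]
        den = w.sum(axis=0)
        num = values @ w
        out = np.divide(num, den, out=np.zeros_like(den), where=den > 0)
        return out.reshape(self._shape)


def _cap_log(values: np.ndarray, cap: float) -> np.ndarray:
    return np.clip(values, -np.log(cap), np.log(cap))


# ---------------------------------------------------------------------------
# total-PM2.5 fusion
# ---------------------------------------------------------------------------


def fuse_total(
    sim: xr.DataArray,
    observations: pd.DataFrame,
    sites: pd.DataFrame,
    grid: GridDefinition,
    config: FusionConfig = FusionConfig(),
) -> xr.DataArray:
    """Fuse the simulated total-PM2.5 field with monitor observations."""
    validate_sites(sites, grid)
    obs = _collocate(observations, sites, sim, TOTAL)
    if len(obs) == 0:
        raise DegenerateInputError("no usable total-PM2.5 observation/model pairs")

    pooled = _PolyCorrection(
        obs["sim"].to_numpy(), obs["value"].to_numpy(), config.polynomial_degree
    )

    # One canonical (row, col) list for the IDW; observations aggregate to it.
    cells = obs[["row", "col"]].drop_duplicates().reset_index(drop=True)
    cell_key = {(r, c): i for i, (r, c) in enumerate(zip(cells["row"], cells["col"]))}
    idw = _IDWInterpolator(
        grid, cells["row"].to_numpy(), cells["col"].to_numpy(),
        config.idw_power, config.idw_radius_km,
    )

    n_days = sim.sizes["time"]
    fused = np.empty_like(sim.values)
    by_day = dict(tuple(obs.groupby("day")))
    for t in range(n_days):
        day_obs = by_day.get(t)
        if day_obs is not None and len(day_obs) >= config.min_pairs_per_day:
            correct = _PolyCorrection(
                day_obs["sim"].to_numpy(), day_obs["value"].to_numpy(),
                config.polynomial_degree,
            )
        else:
            correct = pooled
        corrected = correct(sim.values[t])

        if day_obs is not None and len(day_obs):
            at_sites = corrected[day_obs["row"].to_numpy(int), day_obs["col"].to_numpy(int)]
            log_r = np.log(
                np.maximum(day_obs["value"].to_numpy(), 0.0) + config.denom_floor
            ) - np.log(np.maximum(at_sites, config.denom_floor) + config.denom_floor)
            log_r = _cap_log(log_r, config.ratio_cap)
            keys = [cell_key[(r, c)] for r, c in zip(day_obs["row"], day_obs["col"])]
            frame = pd.DataFrame({"k": keys, "lr": log_r}).groupby("k")["lr"].mean()
            ratio = np.exp(idw.interpolate(frame.index.to_numpy(), frame.to_numpy()))
        else:
            ratio = 1.0
        fused[t] = np.maximum(corrected * ratio, config.concentration_floor)

    return make_field(fused, pd.DatetimeIndex(sim["time"].values), TOTAL, "fused")


def fuse_pf_total(
    delta_sim: xr.DataArray,
    sim_total: xr.DataArray,
    fused_total: xr.DataArray,
    config: FusionConfig = FusionConfig(),
) -> xr.DataArray:
    """Observation-adjusted prescribed-fire impact on total PM2.5.

    Scales the simulated impact by fused/simulated total, so the simulated
    PF *fraction* of the total carries over to the fused total wherever the
    cap and denominator floor are inactive.
    """
    check_aligned(delta_sim, sim_total, fused_total, what="fusion inputs")
    multiplier = fused_total.values / np.maximum(sim_total.values, config.denom_floor)
    multiplier = np.minimum(multiplier, config.ratio_cap)
    values = delta_sim.values * multiplier
    return make_field(
        values, pd.DatetimeIndex(delta_sim["time"].values),
        delta_sim.attrs.get("species", TOTAL), "fused_delta_pf",
    )


# ---------------------------------------------------------------------------
# species-ratio fusion
# ---------------------------------------------------------------------------


def _interp_in_time(day_idx: np.ndarray, values: np.ndarray, n_days: int) -> np.ndarray:
    """Linear interpolation over days, held constant beyond the endpoints."""
    if len(day_idx) == 1:
        return np.full(n_days, values[0])
    return np.interp(np.arange(n_days), day_idx, values)


def fuse_species_ratios(
    sim_fields: xr.Dataset,
    observations: pd.DataFrame,
    sites: pd.DataFrame,
    fused_total: xr.DataArray,
    grid: GridDefinition,
    config: FusionConfig = FusionConfig(),
) -> tuple[xr.Dataset, xr.Dataset]:
    """Fuse species-to-total ratios and derive fused species concentrations.

    Returns ``(ratios, concentrations)``: per-species ratio fields in
    [0, 1] summing to one across {EC, OC, NO3, SO4, OTHER} at every
    cell-day, and the fused species concentration fields (ratio x fused
    total), which therefore sum exactly to the fused total.

    Observed ratios use the observed species and the *same sampler's*
    observed total on the same day.  Corrections (observed/simulated ratio)
    are interpolated linearly in time across each site's sampling days and
    by tapered IDW in space.
    """
    validate_sites(sites, grid)
    check_aligned(sim_fields[TOTAL], fused_total, what="species fusion inputs")
    n_days = fused_total.sizes["time"]
    sim_tot = np.maximum(sim_fields[TOTAL].values, config.denom_floor)
    ratio_floor = 1e-6  # below this a simulated ratio carries no signal

    spec_obs = observations[observations["species"].isin(SPECIES)]
    if len(spec_obs) == 0:
        raise DegenerateInputError("no speciation observations to fuse")

    # Observed totals from the same sampler, keyed by (site, date).
    totals = observations[observations["species"] == TOTAL].set_index(["site", "date"])[
        "value"
    ]

    site_rows = sites.set_index("id")
    spec_sites = sites[sites["kind"] == "speciation"].reset_index(drop=True)
    if len(spec_sites) == 0:
        raise DegenerateInputError("no speciation sites in the site table")
    idw = _IDWInterpolator(
        grid, spec_sites["row"].to_numpy(), spec_sites["col"].to_numpy(),
        config.idw_power, config.idw_radius_km,
    )
    spec_site_idx = {sid: i for i, sid in enumerate(spec_sites["id"])}

    dates = pd.DatetimeIndex(fused_total["time"].values)
    pos = pd.Series(np.arange(n_days), index=dates)

    raw_ratios: dict[str, np.ndarray] = {}
    for sp in SPECIES:
        r_sim = sim_fields[sp].values / sim_tot

        # log-corrections per speciation site, gap-filled in time
        site_logc: dict[int, np.ndarray] = {}
        for sid, group in spec_obs[spec_obs["species"] == sp].groupby("site"):
            if sid not in spec_site_idx:
                continue
            srow = site_rows.loc[sid]
            day_idx, logc = [], []
            for _, o in group.sort_values("date").iterrows():
                tot = totals.get((sid, o["date"]))
                if tot is None or o["date"] not in pos.index:
                    continue
                t = int(pos.loc[o["date"]])
                r_obs = o["value"] / max(tot, config.denom_floor)
                r_mod = max(r_sim[t, srow["row"], srow["col"]], ratio_floor)
                day_idx.append(t)
                logc.append(np.log(max(r_obs, ratio_floor) / r_mod))
            if day_idx:
                series = _interp_in_time(np.asarray(day_idx), np.asarray(logc), n_days)
                site_logc[spec_site_idx[sid]] = _cap_log(series, config.ratio_cap)

        if site_logc:
            idxs = np.asarray(sorted(site_logc))
            stack = np.stack([site_logc[i] for i in idxs])  # (n_used, n_days)
            corr = np.stack(
                [idw.interpolate(idxs, stack[:, t]) for t in range(n_days)]
            )
        else:
            corr = np.zeros((n_days,) + grid.shape)
        raw_ratios[sp] = np.clip(r_sim * np.exp(corr), 0.0, 1.0)

    # Renormalize the species vector to close the mass budget.
    total_ratio = np.sum([raw_ratios[sp] for sp in SPECIES], axis=0)
    safe = np.maximum(total_ratio, ratio_floor)
    equal_share = 1.0 / len(SPECIES)
    ratios, concentrations = {}, {}
    for sp in SPECIES:
        r = np.where(total_ratio > ratio_floor, raw_ratios[sp] / safe, equal_share)
        ratios[sp] = make_field(r, dates, sp, "fused", units="1")
        concentrations[sp] = make_field(r * fused_total.values, dates, sp, "fused")
    return xr.Dataset(ratios), xr.Dataset(concentrations)


def fuse_pf_species(
    delta_spe_sim: xr.DataArray,
    sim_spe: xr.DataArray,
    fused_spe: xr.DataArray,
    config: FusionConfig = FusionConfig(),
) -> xr.DataArray:
    """Observation-adjusted prescribed-fire impact for one species.

    Same scaling as :func:`fuse_pf_total`, with the species' own fused and
    simulated fields.
    """
    check_aligned(delta_spe_sim, sim_spe, fused_spe, what="species impact inputs")
    multiplier = fused_spe.values / np.maximum(sim_spe.values, config.denom_floor)
    multiplier = np.minimum(multiplier, config.ratio_cap)
    return make_field(
        delta_spe_sim.values * multiplier,
        pd.DatetimeIndex(delta_spe_sim["time"].values),
        delta_spe_sim.attrs.get("species", ""),
        "fused_delta_pf",
    )


# ---------------------------------------------------------------------------
# end-to-end fusion of a study
# ---------------------------------------------------------------------------


def run_fusion(
    model_pair,
    observations: pd.DataFrame,
    sites: pd.DataFrame,
    config: FusionConfig = FusionConfig(),
) -> dict[str, xr.Dataset | xr.DataArray]:
    """Full fusion of a paired simulation against a monitor network.

    Excludes near-road sites, fuses the total, fuses species ratios, and
    produces observation-adjusted prescribed-fire impacts for the total and
    every species.  Returns a dict with keys ``fused_total``,
    ``fused_species`` (Dataset), ``ratio_fields`` (Dataset),
    ``delta_sim`` (Dataset), ``fused_delta_total`` and ``fused_delta_species``
    (Dataset).
    """
    from .attribution import pf_delta_all_species

    grid = model_pair.grid
    obs = exclude_near_road(observations, sites)
    sim_all = model_pair.all_emissions
    delta = pf_delta_all_species(model_pair)

    fused_total = fuse_total(sim_all[TOTAL], obs, sites, grid, config)
    ratio_fields, fused_species = fuse_species_ratios(
        sim_all, obs, sites, fused_total, grid, config
    )
    fused_delta_total = fuse_pf_total(delta[TOTAL], sim_all[TOTAL], fused_total, config)
    fused_delta_species = xr.Dataset(
        {
            sp: fuse_pf_species(delta[sp], sim_all[sp], fused_species[sp], config)
            for sp in SPECIES
        }
    )
    return {
        "fused_total": fused_total,
        "fused_species": fused_species,
        "ratio_fields": ratio_fields,
        "delta_sim": delta,
        "fused_delta_total": fused_delta_total,
        "fused_delta_species": fused_delta_species,
    }
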