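"""Synthetic study generator.

This module manufactures every input the attribution/fusion pipeline needs,
with known ground truth, so that each downstream stage can be tested
without any external data:

* a *burn truth* event record with seasonal structure (JFMA-heavy, the
  southeastern prescribed-burning calendar) and heavy-tailed log-normal
  areas;
* degraded views of the truth: a satellite-style record that misses small
  fires and systematically over-reports area, and a permit-style record
  that covers only part of the region but reports areas accurately;
* a toy linear dispersion forward model producing paired daily
  concentration fields (baseline vs. prescribed-fire emissions removed) per
  species — an isotropic Gaussian kernel with a per-day wind displacement
  and a fixed ventilation volume, linear in emissions by construction;
* "model" fields: the truth fields degraded by per-species multiplicative
  biases and a smooth multiplicative error field, emulating the systematic
  and structural errors of a real chemical-transport model;
* monitor networks and observations: unbiased noisy samples of the truth at
  fixed sites, daily for total-PM2.5 monitors and 1-in-3-day for speciation
  monitors.

Ground truth is unbiased in the observations and distorted in the model
fields, which makes "fusion moves the model toward the truth" a directly
testable statement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, InputError
from .fields import SPECIES, TOTAL, ScenarioPair, make_dates, make_field
from .grid import GridDefinition
from .records import empty_events, make_events, validate_events, validate_sites
from .seasons import DEFAULT_SEASONS, SeasonDefinition

__all__ = [
    "KernelParams",
    "ModelErrorParams",
    "SyntheticStudy",
    "DEFAULT_SEASONAL_WEIGHTS",
    "DEFAULT_BACKGROUND",
    "DEFAULT_MODEL_BIASES",
    "generate_burn_truth",
    "degrade_to_satellite",
    "sample_permits",
    "simulate_concentration_fields",
    "bias_model_fields",
    "generate_sites",
    "generate_observations",
    "default_fixture",
]

#: Seasonal shares of prescribed burned area (fractions of the period total).
DEFAULT_SEASONAL_WEIGHTS: dict[str, float] = {"JFMA": 0.541, "MJJAS": 0.221, "OND": 0.238}

#: Regional background concentrations (ug/m3) for the non-fire portion of
#: each PM2.5 component; the implied total background is their sum (6.0).
DEFAULT_BACKGROUND: dict[str, float] = {
    "EC": 0.18,
    "OC": 1.30,
    "NO3": 0.30,
    "SO4": 1.30,
    "OTHER": 2.92,
}

#: Multiplicative model-vs-truth biases per species: the model
#: underestimates total PM2.5 by ~20%, EC by ~29%, NO3 by ~10% and SO4 by
#: ~21%, and overestimates OC by ~42%. OTHER is mildly underestimated.
DEFAULT_MODEL_BIASES: dict[str, float] = {
    TOTAL: 0.80,
    "EC": 0.71,
    "OC": 1.42,
    "NO3": 0.90,
    "SO4": 0.79,
    "OTHER": 0.85,
}

TONS_TO_UG = 1.0e12
KM2_TO_M2 = 1.0e6


@dataclass(frozen=True)
class KernelParams:
    """Toy dispersion kernel: isotropic Gaussian plus daily wind drift.

    ``scale_km`` is the Gaussian dispersion length; ``wind_sd_km`` the
    standard deviation of the per-day random plume displacement (one shared
    offset per day); ``mixing_height_m`` is a ventilation-equivalent column
    depth converting emitted mass to a 24 h mean concentration: each day's
    emissions are diluted into ``cell_area x mixing_height_m`` per cell.
    The depth folds boundary-layer height and day-scale ventilation into a
    single constant, sized so that realistic regional burn activity yields
    regional prescribed-fire PM2.5 impacts of a few tenths of a ug/m3 with
    plume maxima of tens of ug/m3.
    """

    scale_km: float = 18.0
    wind_sd_km: float = 24.0
    mixing_height_m: float = 12_000.0

    def __post_init__(self) -> None:
        if self.scale_km <= 0:
            raise ConfigurationError("kernel scale_km must be positive")
        if self.wind_sd_km < 0 or self.mixing_height_m <= 0:
            raise ConfigurationError("invalid kernel parameters")


@dataclass(frozen=True)
class ModelErrorParams:
    """Smooth multiplicative error applied to truth to make model fields.

    The error is ``bias_sp * exp(delta(x, t))`` with ``delta`` a mean-zero
    Gaussian random field, spatially smoothed to ``corr_km`` and AR(1) in
    time with coefficient ``ar1``; ``exp(delta)`` is rescaled to mean 1 so
    the species bias factors control the mean bias.  A spatially structured
    error (unlike white noise) is what data fusion can actually correct
    from neighbouring monitors, and is how transport-model errors behave.
    """

    sigma: float = 0.30
    corr_km: float = 100.0
    ar1: float = 0.8

    def __post_init__(self) -> None:
        if self.sigma < 0 or not (0 <= self.ar1 < 1) or self.corr_km <= 0:
            raise ConfigurationError("invalid model-error parameters")


# ---------------------------------------------------------------------------
# burn records
# ---------------------------------------------------------------------------


def _seasonal_day_probabilities(
    dates: pd.DatetimeIndex,
    seasonal_weights: dict[str, float],
    seasons: SeasonDefinition,
) -> np.ndarray:
    w = dict(seasonal_weights)
    if any(v < 0 for v in w.values()) or abs(sum(w.values()) - 1.0) > 1e-6:
        raise ConfigurationError("seasonal weights must be nonnegative and sum to 1")
    labels = seasons.of_dates(dates)
    p = np.zeros(len(dates))
    for season, weight in w.items():
        mask = labels == season
        if mask.any():
            p[mask] = weight / mask.sum()
    total = p.sum()
    if total <= 0:
        raise ConfigurationError("no simulation day falls in a season with positive weight")
    return p / total


def generate_burn_truth(
    grid: GridDefinition,
    n_days: int,
    seasonal_weights: dict[str, float] | None = None,
    mean_daily_events: float = 10.0,
    median_area_acres: float = 50.0,
    area_sigma_log: float = 1.2,
    prescribed_fraction: float = 0.7,
    private_fraction: float = 0.84,
    start: str = "2020-09-15",
    seasons: SeasonDefinition = DEFAULT_SEASONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the ground-truth fire record for the simulation period.

    Event count is Poisson with mean ``mean_daily_events * n_days``; dates
    follow the configured seasonal area weights (uniform within a season);
    areas are log-normal (heavy-tailed positive, like permit records);
    locations are uniform over the grid.  Roughly 70% of events are
    prescribed burns (the share of satellite fire detections classified as
    prescribed in the region) and 84% sit on private land.
    """
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    if mean_daily_events < 0:
        raise ConfigurationError("mean_daily_events must be nonnegative")
    if median_area_acres <= 0 or area_sigma_log < 0:
        raise ConfigurationError("area distribution parameters must be positive")
    rng = np.random.default_rng(seed)
    dates = make_dates(start, n_days)
    p_day = _seasonal_day_probabilities(dates, seasonal_weights or DEFAULT_SEASONAL_WEIGHTS, seasons)
    n = rng.poisson(mean_daily_events * n_days)
    if n == 0:
        return empty_events()
    day_idx = rng.choice(len(dates), size=n, p=p_day)
    areas = rng.lognormal(mean=np.log(median_area_acres), sigma=area_sigma_log, size=n)
    rows = rng.integers(0, grid.n_rows, size=n)
    cols = rng.integers(0, grid.n_cols, size=n)
    burn_types = np.where(rng.random(n) < prescribed_fraction, "prescribed", "wildfire")
    ownerships = np.where(rng.random(n) < private_fraction, "private", "federal")
    events = make_events(
        dates[day_idx], rows, cols, areas, "truth", burn_types, ownerships
    ).sort_values("date", kind="stable").reset_index(drop=True)
    return events


def degrade_to_satellite(
    truth: pd.DataFrame,
    min_detectable_area: float = 1.18,
    overreport_factor: float = 0.66,
    miss_probability: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Degrade the truth record into a satellite-style detection record.

    Fires below the minimum detectable area (1.18 acres for the satellite
    product emulated here, versus 0.03 acres in permit records) are never
    detected; surviving fires are missed at random (cloud cover, overpass
    timing); detected areas are inflated by ``1 / overreport_factor``, so
    with the default 0.66 satellite areas systematically exceed truth.
    """
    if overreport_factor <= 0:
        raise ConfigurationError("overreport_factor must be positive")
    if not (0 <= miss_probability < 1):
        raise ConfigurationError("miss_probability must be in [0, 1)")
    validate_events(truth)
    rng = np.random.default_rng(seed)
    detected = truth[truth["area_acres"] >= min_detectable_area]
    keep = rng.random(len(detected)) < (1.0 - miss_probability)
    out = detected.loc[keep].copy()
    out["area_acres"] = out["area_acres"] / overreport_factor
    out["source"] = "satellite"
    return out.reset_index(drop=True)


def sample_permits(
    truth: pd.DataFrame,
    coverage_probability: float = 0.5,
    seed: int = 0,
    mode: str = "events",
    grid: GridDefinition | None = None,
) -> pd.DataFrame:
    """Thin the truth record into an incomplete permit record.

    Permit systems do not cover the whole region; retained areas are copied
    unchanged — permits are treated as the accurate area source.  Two
    coverage structures are available:

    ``events``
        each event retained independently with ``coverage_probability``;
    ``region``
        permits are complete inside a contiguous block of grid columns
        covering ``coverage_probability`` of the domain and absent outside
        it — the structure of real permit availability, where some states
        keep complete records and others none.  Region-structured coverage
        is what makes permit-vs-satellite calibration well-posed: under
        event-level thinning, satellite detections with a randomly missing
        permit enter the regression as false zeros and the fitted scaling
        absorbs the coverage rate.
    """
    if not (0 < coverage_probability <= 1):
        raise ConfigurationError("coverage_probability must be in (0, 1]")
    validate_events(truth)
    if mode == "events":
        rng = np.random.default_rng(seed)
        keep = rng.random(len(truth)) < coverage_probability
    elif mode == "region":
        if grid is None:
            raise ConfigurationError("region-structured permit coverage needs the grid")
        n_covered = int(np.ceil(coverage_probability * grid.n_cols))
        keep = truth["col"].to_numpy() < n_covered
    else:
        raise ConfigurationError(f"unknown permit coverage mode {mode!r}")
    out = truth.loc[keep].copy()
    out["source"] = "permit"
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def _day_kernels(
    grid: GridDefinition,
    source_rows: np.ndarray,
    source_cols: np.ndarray,
    offset_xy_km: tuple[float, float],
    scale_km: float,
) -> np.ndarray:
    """Normalized dispersion weights, shape (n_sources, n_rows, n_cols).

    Each source's Gaussian is centred at its cell centre shifted by the
    day's wind offset and normalized to sum to 1 over the grid, so emitted
    mass is conserved on the domain.
    """
    xx, yy = grid.cell_centers_km()
    ox, oy = offset_xy_km
    x0 = grid.origin[0] + (source_cols + 0.5) * grid.cell_size_km + ox
    y0 = grid.origin[1] + (source_rows + 0.5) * grid.cell_size_km + oy
    dx = xx[None, :, :] - x0[:, None, None]
    dy = yy[None, :, :] - y0[:, None, None]
    w = np.exp(-(dx**2 + dy**2) / (2.0 * scale_km**2))
    sums = w.sum(axis=(1, 2), keepdims=True)
    return w / sums


def _disperse(
    grid: GridDefinition,
    emissions: xr.Dataset,
    offsets_km: np.ndarray,
    kernel: KernelParams,
) -> dict[str, np.ndarray]:
    """Run the toy forward model for one emissions inventory.

    ``emissions`` holds per-species daily gridded masses in tons; the
    return value maps species to (time, row, col) concentration additions
    in ug/m3.
    """
    species = list(emissions.data_vars)
    n_days = emissions.sizes["time"]
    out = {sp: np.zeros((n_days, grid.n_rows, grid.n_cols)) for sp in species}
    conc_per_ton = TONS_TO_UG / (grid.cell_area_km2 * KM2_TO_M2 * kernel.mixing_height_m)
    stacked = np.stack([emissions[sp].values for sp in species])  # (spe, t, r, c)
    any_mass = stacked.sum(axis=0)  # (t, r, c)
    for t in range(n_days):
        rows, cols = np.nonzero(any_mass[t] > 0)
        if rows.size == 0:
            continue
        kernels = _day_kernels(grid, rows, cols, tuple(offsets_km[t]), kernel.scale_km)
        masses = stacked[:, t, rows, cols]  # (spe, n_src)
        fields = np.tensordot(masses, kernels, axes=(1, 0))  # (spe, r, c)
        for i, sp in enumerate(species):
            out[sp][t] = fields[i] * conc_per_ton
    return out


def simulate_concentration_fields(
    grid: GridDefinition,
    pf_emissions: xr.Dataset,
    background: dict[str, float] | None = None,
    kernel: KernelParams = KernelParams(),
    other_emissions: xr.Dataset | None = None,
    seed: int = 0,
) -> ScenarioPair:
    """Produce the paired daily concentration fields for zero-out attribution.

    The baseline member receives background plus plumes from all emissions;
    the ``no_pf`` member is computed identically with the prescribed-fire
    inventory removed (non-fire sources are folded into the constant
    per-species background; ``other_emissions`` carries non-prescribed
    fires, which remain in both members).  The forward model is linear in
    emissions by construction, so the member difference equals the field
    simulated from the prescribed-fire inventory alone.

    Total PM2.5 is the sum of the five component fields, closing the mass
    budget exactly.
    """
    background = dict(DEFAULT_BACKGROUND if background is None else background)
    missing = [sp for sp in SPECIES if sp not in pf_emissions.data_vars]
    if missing:
        raise InputError(f"pf_emissions missing species {missing}")
    if any(v < 0 for v in background.values()):
        raise ConfigurationError("background concentrations must be nonnegative")
    for ds in (pf_emissions, other_emissions):
        if ds is not None and any((ds[sp].values < 0).any() for sp in ds.data_vars):
            raise InputError("emissions must be nonnegative")

    dates = pd.DatetimeIndex(pf_emissions["time"].values)
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, kernel.wind_sd_km, size=(len(dates), 2))

    pf_add = _disperse(grid, pf_emissions, offsets, kernel)
    if other_emissions is not None:
        other_add = _disperse(grid, other_emissions, offsets, kernel)
    else:
        other_add = {sp: 0.0 for sp in SPECIES}

    def build(include_pf: bool) -> xr.Dataset:
        shape = (len(dates), grid.n_rows, grid.n_cols)
        scenario = "all" if include_pf else "no_pf"
        data = {}
        total = np.zeros(shape)
        for sp in SPECIES:
            vals = np.full(shape, background.get(sp, 0.0))
            vals = vals + other_add[sp]
            if include_pf:
                vals = vals + pf_add[sp]
            data[sp] = make_field(vals, dates, sp, scenario)
            total += vals
        data[TOTAL] = make_field(total, dates, TOTAL, scenario)
        return xr.Dataset(data)

    return ScenarioPair(grid=grid, all_emissions=build(True), no_pf=build(False))


def _smooth_error_field(
    shape: tuple[int, int, int],
    cell_size_km: float,
    params: ModelErrorParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multiplicative error exp(delta), mean-one, smooth in space and time."""
    if params.sigma == 0:
        return np.ones(shape)
    noise = rng.standard_normal(shape)
    ar = np.empty_like(noise)
    ar[0] = noise[0]
    innov = np.sqrt(1.0 - params.ar1**2)
    for t in range(1, shape[0]):
        ar[t] = params.ar1 * ar[t - 1] + innov * noise[t]
    sigma_cells = params.corr_km / cell_size_km
    smooth = gaussian_filter(ar, sigma=(0.0, sigma_cells, sigma_cells), mode="nearest")
    smooth = smooth / smooth.std() * params.sigma
    e = np.exp(smooth)
    return e / e.mean()


def bias_model_fields(
    truth_pair: ScenarioPair,
    biases: dict[str, float] | None = None,
    error: ModelErrorParams = ModelErrorParams(),
    seed: int = 0,
) -> ScenarioPair:
    """Degrade truth fields into "model" fields.

    Each species field (in both scenario members) is multiplied by its
    systematic bias factor and by one shared smooth multiplicative error
    field, emulating a transport model whose errors are spatially and
    temporally coherent.  The same error applies to both members, as a real
    paired zero-out experiment shares meteorology and parametrizations.
    """
    biases = dict(DEFAULT_MODEL_BIASES if biases is None else biases)
    rng = np.random.default_rng(seed)
    shape = tuple(truth_pair.all_emissions[TOTAL].shape)
    efield = _smooth_error_field(shape, truth_pair.grid.cell_size_km, error, rng)

    def degrade(ds: xr.Dataset) -> xr.Dataset:
        out = {}
        for sp in ds.data_vars:
            factor = biases.get(sp)
            if factor is None:
                raise ConfigurationError(f"no model bias configured for species {sp}")
            da = ds[sp].copy()
            da.values = ds[sp].values * factor * efield
            out[sp] = da
        return xr.Dataset(out)

    return ScenarioPair(
        grid=truth_pair.grid,
        all_emissions=degrade(truth_pair.all_emissions),
        no_pf=degrade(truth_pair.no_pf),
    )


# ---------------------------------------------------------------------------
# monitors
# ---------------------------------------------------------------------------


def generate_sites(
    grid: GridDefinition,
    n_total_pm: int = 36,
    n_speciation: int = 12,
    near_road_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Place monitor sites on distinct random cells.

    Total-PM2.5 monitors sample daily; speciation monitors sample every
    third day with a site-specific phase offset, as the real speciation
    networks do.  A fraction of sites is flagged near-road (excluded from
    fusion to avoid local traffic influence).
    """
    n = n_total_pm + n_speciation
    if n > grid.n_cells:
        raise ConfigurationError("more sites requested than grid cells")
    rng = np.random.default_rng(seed)
    flat = rng.choice(grid.n_cells, size=n, replace=False)
    rows, cols = np.divmod(flat, grid.n_cols)
    kinds = ["total_pm"] * n_total_pm + ["speciation"] * n_speciation
    schedules = ["daily"] * n_total_pm + ["one_in_three"] * n_speciation
    sites = pd.DataFrame(
        {
            "id": [f"S{i:03d}" for i in range(n)],
            "row": rows,
            "col": cols,
            "kind": kinds,
            "schedule": schedules,
            "schedule_offset": rng.integers(0, 3, size=n),
            "near_road": rng.random(n) < near_road_fraction,
        }
    )
    return sites


def _schedule_mask(site: pd.Series, n_days: int) -> np.ndarray:
    idx = np.arange(n_days)
    if site["schedule"] == "daily":
        return np.ones(n_days, dtype=bool)
    return (idx % 3) == (site["schedule_offset"] % 3)


def generate_observations(
    truth_fields: xr.Dataset,
    sites: pd.DataFrame,
    noise_sd: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample noisy monitor observations from the truth fields.

    Each observation is truth at the site's cell times ``(1 + eps)`` with
    ``eps ~ Normal(0, noise_sd)``, floored at zero — unbiased multiplicative
    measurement error.  Total-PM monitors report only total PM2.5;
    speciation monitors report the five components and the total from the
    same sampler, on their 1-in-3-day schedule.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be nonnegative")
    validate_sites(sites)
    grid_shape = (truth_fields.sizes["row"], truth_fields.sizes["col"])
    if len(sites) and (
        (sites["row"] >= grid_shape[0]).any() or (sites["col"] >= grid_shape[1]).any()
    ):
        raise InputError("monitor site off the field grid")
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(truth_fields["time"].values)
    n_days = len(dates)
    frames = []
    for _, site in sites.iterrows():
        mask = _schedule_mask(site, n_days)
        day_idx = np.nonzero(mask)[0]
        species = (TOTAL,) if site["kind"] == "total_pm" else SPECIES + (TOTAL,)
        for sp in species:
            truth = truth_fields[sp].values[day_idx, site["row"], site["col"]]
            eps = rng.normal(0.0, noise_sd, size=truth.size) if noise_sd > 0 else 0.0
            values = np.maximum(truth * (1.0 + eps), 0.0)
            frames.append(
                pd.DataFrame(
                    {
                        "site": site["id"],
                        "date": dates[day_idx],
                        "species": sp,
                        "value": values,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["site", "date", "species", "value"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# the default end-to-end fixture
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    """Bundle of every synthetic input/intermediate for one study period."""

    grid: GridDefinition
    dates: pd.DatetimeIndex
    seasons: SeasonDefinition
    truth_events: pd.DataFrame
    satellite_events: pd.DataFrame
    permit_events: pd.DataFrame
    pf_emissions: xr.Dataset
    other_emissions: xr.Dataset
    truth_pair: ScenarioPair
    model_pair: ScenarioPair
    sites: pd.DataFrame
    observations: pd.DataFrame


def default_fixture(seed: int = 0, n_days: int = 120, grid_size: int = 30) -> SyntheticStudy:
    """Generate the default desk-scale study.

    A 30x30 grid of 12 km cells over 120 days (mid-September through
    mid-January, touching all three burning seasons), with burn activity,
    plume magnitudes, monitor densities, model biases and observation noise
    chosen to mirror the character of a multi-state southeastern-US study
    period at roughly one tenth of its spatial extent.
    """
    from .emissions import EmissionFactorTable, compute_emissions

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]

    grid = GridDefinition(n_rows=grid_size, n_cols=grid_size, cell_size_km=12.0)
    dates = make_dates("2020-09-15", n_days)

    truth = generate_burn_truth(grid, n_days=n_days, start="2020-09-15", seed=seeds[0])
    satellite = degrade_to_satellite(truth, seed=seeds[1])
    permits = sample_permits(truth, seed=seeds[2], mode="region", grid=grid)

    table = EmissionFactorTable()
    pf_events = truth[truth["burn_type"] == "prescribed"]
    other_events = truth[truth["burn_type"] != "prescribed"]
    pf_emissions = compute_emissions(pf_events, table, grid, dates)
    other_emissions = compute_emissions(other_events, table, grid, dates)

    truth_pair = simulate_concentration_fields(
        grid, pf_emissions, other_emissions=other_emissions, seed=seeds[3]
    )
    model_pair = bias_model_fields(truth_pair, seed=seeds[4])

    sites = generate_sites(grid, seed=seeds[5])
    observations = generate_observations(truth_pair.all_emissions, sites, seed=seeds[5])

    return SyntheticStudy(
        grid=grid,
        dates=dates,
        seasons=DEFAULT_SEASONS,
        truth_events=truth,
        satellite_events=satellite,
        permit_events=permits,
        pf_emissions=pf_emissions,
        other_emissions=other_emissions,
        truth_pair=truth_pair,
        model_pair=model_pair,
        sites=sites,
        observations=observations,
    )
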