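"""Serialized interfaces between pipeline stages.

Gridded fields travel as NetCDF (classic format via the scipy backend)
with dimensions ``(time, row, col)``, one variable per species (and
scenario, for paired runs) and a CF-style ``units`` attribute.  Events,
sites and observations travel as CSV with ISO-8601 dates.  Region polygons
are read from GeoJSON in grid km coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import xarray as xr
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

from .errors import InputError
from .fields import ScenarioPair
from .grid import GridDefinition
from .records import (
    EVENT_COLUMNS,
    OBS_COLUMNS,
    SITE_COLUMNS,
    validate_events,
    validate_observations,
    validate_sites,
)

_ENGINE = "scipy"

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_pair",
    "read_pair",
    "write_events",
    "read_events",
    "write_sites",
    "read_sites",
    "write_observations",
    "read_observations",
    "read_regions_geojson",
]


def _grid_attrs(grid: GridDefinition) -> dict:
    return {
        "grid_n_rows": grid.n_rows,
        "grid_n_cols": grid.n_cols,
        "grid_cell_size_km": grid.cell_size_km,
        "grid_origin_x_km": grid.origin[0],
        "grid_origin_y_km": grid.origin[1],
    }


def grid_from_attrs(attrs: dict) -> GridDefinition:
    try:
        return GridDefinition(
            n_rows=int(attrs["grid_n_rows"]),
            n_cols=int(attrs["grid_n_cols"]),
            cell_size_km=float(attrs["grid_cell_size_km"]),
            origin=(float(attrs["grid_origin_x_km"]), float(attrs["grid_origin_y_km"])),
        )
    except KeyError as exc:
        raise InputError(f"NetCDF file lacks grid metadata attribute {exc}") from exc


def write_dataset(ds: xr.Dataset, path: str | Path, grid: GridDefinition | None = None) -> None:
    ds = ds.copy()
    if grid is not None:
        ds.attrs.update(_grid_attrs(grid))
    ds.to_netcdf(path, engine=_ENGINE)


def read_dataset(path: str | Path) -> xr.Dataset:
    return xr.load_dataset(path, engine=_ENGINE)


def write_pair(pair: ScenarioPair, path: str | Path) -> None:
    """Serialize a scenario pair as one file, variables ``{species}_{scenario}``."""
    merged = xr.Dataset(attrs=_grid_attrs(pair.grid))
    for scenario, ds in (("all", pair.all_emissions), ("no_pf", pair.no_pf)):
        for sp in ds.data_vars:
            merged[f"{sp}_{scenario}"] = ds[sp]
    merged.to_netcdf(path, engine=_ENGINE)


def read_pair(path: str | Path) -> ScenarioPair:
    merged = xr.load_dataset(path, engine=_ENGINE)
    grid = grid_from_attrs(merged.attrs)
    members: dict[str, dict[str, xr.DataArray]] = {"all": {}, "no_pf": {}}
    for name in merged.data_vars:
        if name.endswith("_no_pf"):
            members["no_pf"][name[: -len("_no_pf")]] = merged[name]
        elif name.endswith("_all"):
            members["all"][name[: -len("_all")]] = merged[name]
    if not members["all"] or not members["no_pf"]:
        raise InputError(f"{path} does not contain a scenario pair")
    return ScenarioPair(
        grid=grid,
        all_emissions=xr.Dataset(members["all"]),
        no_pf=xr.Dataset(members["no_pf"]),
    )


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events)
    out = events.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out[EVENT_COLUMNS].to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, parse_dates=["date"])
    validate_events(events)
    return events[EVENT_COLUMNS]


def write_sites(sites: pd.DataFrame, path: str | Path) -> None:
    validate_sites(sites)
    sites[SITE_COLUMNS].to_csv(path, index=False)


def read_sites(path: str | Path) -> pd.DataFrame:
    sites = pd.read_csv(path)
    validate_sites(sites)
    return sites[SITE_COLUMNS]


def write_observations(obs: pd.DataFrame, path: str | Path) -> None:
    validate_observations(obs)
    out = obs.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out[OBS_COLUMNS].to_csv(path, index=False)


def read_observations(path: str | Path) -> pd.DataFrame:
    obs = pd.read_csv(path, parse_dates=["date"])
    validate_observations(obs)
    return obs[OBS_COLUMNS]


def read_regions_geojson(path: str | Path) -> list[tuple[str, BaseGeometry]]:
    """Region polygons from a GeoJSON FeatureCollection in km coordinates.

    Each feature's name comes from its ``name`` (or ``id``) property.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise InputError("regions file must be a GeoJSON FeatureCollection")
    regions = []
    for i, feature in enumerate(doc.get("features", [])):
        props = feature.get("properties") or {}
        name = str(props.get("name", props.get("id", f"region_{i}")))
        regions.append((name, shape(feature["geometry"])))
    if not regions:
        raise InputError("regions file contains no features")
    return regions
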