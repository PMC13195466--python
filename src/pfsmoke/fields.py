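"""Gridded daily concentration fields and the paired-scenario container.

A *field series* is an :class:`xarray.DataArray` with dims ``(time, row,
col)`` holding daily mean concentrations in ug/m3 for one species and one
scenario.  Species and scenario labels travel in ``attrs``.  A collection
of species for one scenario is an :class:`xarray.Dataset` with one variable
per species.

Scenario labels
---------------
``all``            baseline run, every emission source active
``no_pf``          identical run with prescribed-fire emissions removed
``delta_pf``       pointwise difference ``all - no_pf`` (may be negative)
``fused``          observation-fused field
``fused_delta_pf`` observation-adjusted prescribed-fire impact
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .errors import InputError
from .grid import GridDefinition

__all__ = [
    "SPECIES",
    "TOTAL",
    "ALL_SPECIES",
    "SCENARIOS",
    "make_field",
    "make_dates",
    "check_aligned",
    "field_grid_shape",
    "ScenarioPair",
]

#: Chemical components of PM2.5 tracked by the pipeline. ``OTHER`` closes
#: the mass budget: the five components sum to total PM2.5.
SPECIES: tuple[str, ...] = ("EC", "OC", "NO3", "SO4", "OTHER")

#: Total (unspeciated) PM2.5 mass.
TOTAL = "PM25_TOT"

ALL_SPECIES: tuple[str, ...] = SPECIES + (TOTAL,)

SCENARIOS: tuple[str, ...] = ("all", "no_pf", "delta_pf", "fused", "fused_delta_pf")


def make_dates(start: str | np.datetime64, n_days: int) -> pd.DatetimeIndex:
    """Consecutive daily timestamps starting at ``start``."""
    return pd.date_range(start=start, periods=n_days, freq="D")


def make_field(
    values: np.ndarray,
    dates: pd.DatetimeIndex,
    species: str,
    scenario: str,
    units: str = "ug m-3",
) -> xr.DataArray:
    """Wrap a ``(time, row, col)`` array as a labelled field series."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.shape[0] != len(dates):
        raise InputError(
            f"field values must be (time, row, col) with {len(dates)} days, got {values.shape}"
        )
    if scenario not in SCENARIOS:
        raise InputError(f"unknown scenario {scenario!r}")
    da = xr.DataArray(
        values,
        dims=("time", "row", "col"),
        coords={"time": dates},
        name=f"{species}_{scenario}",
        attrs={"species": species, "scenario": scenario, "units": units},
    )
    return da


def field_grid_shape(field: xr.DataArray) -> tuple[int, int]:
    return (field.sizes["row"], field.sizes["col"])


def check_aligned(*fields: xr.DataArray, what: str = "fields") -> None:
    """Raise :class:`InputError` unless all fields share shape and dates."""
    first = fields[0]
    for f in fields[1:]:
        if f.sizes != first.sizes:
            raise InputError(f"misaligned {what}: shapes {dict(first.sizes)} vs {dict(f.sizes)}")
        if not np.array_equal(f["time"].values, first["time"].values):
            raise InputError(f"misaligned {what}: date axes differ")


@dataclass
class ScenarioPair:
    """The two paired chemical-transport runs used for zero-out attribution.

    Both members are Datasets with one variable per species (named after the
    species), sharing grid, dates and species set.  ``all_emissions`` is the
    baseline run; ``no_pf`` excludes prescribed-fire emissions.
    """

    grid: GridDefinition
    all_emissions: xr.Dataset
    no_pf: xr.Dataset

    def __post_init__(self) -> None:
        a, b = self.all_emissions, self.no_pf
        if set(a.data_vars) != set(b.data_vars):
            raise InputError("scenario pair members carry different species sets")
        if dict(a.sizes) != dict(b.sizes):
            raise InputError("scenario pair members have different shapes")
        if not np.array_equal(a["time"].values, b["time"].values):
            raise InputError("scenario pair members cover different dates")
        if (a.sizes["row"], a.sizes["col"]) != self.grid.shape:
            raise InputError("scenario pair does not match its grid definition")
        for name, ds in (("all_emissions", a), ("no_pf", b)):
            for sp in ds.data_vars:
                if not np.isfinite(ds[sp].values).all():
                    raise InputError(f"{name}[{sp}] contains non-finite values")
                if (ds[sp].values < 0).any():
                    raise InputError(f"{name}[{sp}] contains negative concentrations")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.all_emissions.data_vars)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.all_emissions["time"].values)
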