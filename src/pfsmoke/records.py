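"""Tabular record schemas: burn events, monitor sites, observations.

Collections of records are plain :class:`pandas.DataFrame` objects with the
column sets below; the helpers here build and validate them.  Dates are
``datetime64[ns]`` in memory and ISO-8601 strings on disk.

Burn events (``EVENT_COLUMNS``)
    one fire record per row: date, grid cell, area in acres, provenance
    (``truth`` | ``permit`` | ``satellite``), burn type (``prescribed`` |
    ``wildfire``) and ownership (``private`` | ``federal``).

Monitor sites (``SITE_COLUMNS``)
    one row per monitor: id, grid cell, kind (``total_pm`` measures only
    total PM2.5; ``speciation`` measures the components and the total),
    sampling schedule (``daily`` | ``one_in_three`` with a per-site phase
    offset) and a near-road flag.

Observations (``OBS_COLUMNS``)
    one monitor-day-species measurement per row, ug/m3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError
from .grid import GridDefinition

__all__ = [
    "EVENT_COLUMNS",
    "SITE_COLUMNS",
    "OBS_COLUMNS",
    "EVENT_SOURCES",
    "BURN_TYPES",
    "OWNERSHIPS",
    "empty_events",
    "make_events",
    "validate_events",
    "validate_sites",
    "validate_observations",
]

EVENT_COLUMNS = ["date", "row", "col", "area_acres", "source", "burn_type", "ownership"]
SITE_COLUMNS = ["id", "row", "col", "kind", "schedule", "schedule_offset", "near_road"]
OBS_COLUMNS = ["site", "date", "species", "value"]

EVENT_SOURCES = ("truth", "permit", "satellite")
BURN_TYPES = ("prescribed", "wildfire")
OWNERSHIPS = ("private", "federal")
SITE_KINDS = ("total_pm", "speciation")
SCHEDULES = ("daily", "one_in_three")


def empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "date": pd.Series(dtype="datetime64[ns]"),
            "row": pd.Series(dtype=int),
            "col": pd.Series(dtype=int),
            "area_acres": pd.Series(dtype=float),
            "source": pd.Series(dtype=object),
            "burn_type": pd.Series(dtype=object),
            "ownership": pd.Series(dtype=object),
        }
    )


def make_events(
    dates,
    rows,
    cols,
    areas_acres,
    source: str,
    burn_types=None,
    ownerships=None,
) -> pd.DataFrame:
    """Assemble an event table from parallel arrays."""
    n = len(areas_acres)
    df = pd.DataFrame(
        {
            "date": pd.DatetimeIndex(dates),
            "row": np.asarray(rows, dtype=int),
            "col": np.asarray(cols, dtype=int),
            "area_acres": np.asarray(areas_acres, dtype=float),
            "source": source,
            "burn_type": (
                np.asarray(burn_types, dtype=object) if burn_types is not None else "prescribed"
            ),
            "ownership": (
                np.asarray(ownerships, dtype=object) if ownerships is not None else "private"
            ),
        }
    )
    return df[EVENT_COLUMNS]


def validate_events(events: pd.DataFrame, grid: GridDefinition | None = None) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise InputError(f"event table missing columns {missing}")
    if len(events) == 0:
        return
    if (events["area_acres"] <= 0).any():
        raise InputError("burn-event areas must be positive")
    bad = set(events["source"]) - set(EVENT_SOURCES)
    if bad:
        raise InputError(f"unknown event source labels {sorted(bad)}")
    if grid is not None:
        grid.validate_cells(events["row"].to_numpy(), events["col"].to_numpy(), "burn event")


def validate_sites(sites: pd.DataFrame, grid: GridDefinition | None = None) -> None:
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise InputError(f"site table missing columns {missing}")
    if sites["id"].duplicated().any():
        raise InputError("site ids must be unique")
    bad = set(sites["kind"]) - set(SITE_KINDS)
    if bad:
        raise InputError(f"unknown site kinds {sorted(bad)}")
    bad = set(sites["schedule"]) - set(SCHEDULES)
    if bad:
        raise InputError(f"unknown schedules {sorted(bad)}")
    if grid is not None and len(sites):
        if not np.all(grid.contains(sites["row"].to_numpy(), sites["col"].to_numpy())):
            raise InputError("monitor site off the grid")


def validate_observations(obs: pd.DataFrame) -> None:
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise InputError(f"observation table missing columns {missing}")
    if len(obs) == 0:
        return
    if (obs["value"] < 0).any():
        raise InputError("observed concentrations must be nonnegative")
    if obs.duplicated(subset=["site", "date", "species"]).any():
        raise InputError("duplicate (site, date, species) observations")
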