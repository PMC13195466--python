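"""Zero-out source attribution by scenario differencing.

The simulated contribution of prescribed fire to a species' concentration
is the pointwise difference between the baseline run and the run with
prescribed-fire emissions removed:

    delta_PF(x, t) = C_all(x, t) - C_no_PF(x, t)

The difference is taken as-is — no clamping — because under nonlinear
atmospheric chemistry a source's removal can locally *raise* some species,
and flooring the delta would silently destroy mass consistency.  Callers
that need nonnegative impacts can clamp at the aggregation stage.
"""

from __future__ import annotations

import xarray as xr

from .errors import InputError
from .fields import ScenarioPair, make_field

__all__ = ["pf_delta", "pf_delta_all_species"]


def pf_delta(pair: ScenarioPair, species: str) -> xr.DataArray:
    """Simulated source-attributable field for one species (``delta_pf``)."""
    if species not in pair.all_emissions.data_vars:
        raise InputError(f"species {species!r} not present in scenario pair")
    values = pair.all_emissions[species].values - pair.no_pf[species].values
    return make_field(values, pair.dates, species, "delta_pf")


def pf_delta_all_species(pair: ScenarioPair) -> xr.Dataset:
    """``pf_delta`` for every species in the pair, as one Dataset."""
    return xr.Dataset({sp: pf_delta(pair, sp) for sp in pair.species})
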