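"""Burning-season calendar.

Prescribed burning in the southeastern US concentrates in the first third
of the year, so the analysis year is split into three seasons:

* ``JFMA`` (January-April): the extensive burning season;
* ``MJJAS`` (May-September): the least active season;
* ``OND`` (October-December): moderate activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["SeasonDefinition", "DEFAULT_SEASONS", "SEASON_ORDER"]

SEASON_ORDER: tuple[str, ...] = ("JFMA", "MJJAS", "OND")


@dataclass(frozen=True)
class SeasonDefinition:
    """Mapping of calendar month (1-12) to a season label.

    Every month must be mapped exactly once.
    """

    month_to_season: dict[int, str] = field(
        default_factory=lambda: {
            1: "JFMA", 2: "JFMA", 3: "JFMA", 4: "JFMA",
            5: "MJJAS", 6: "MJJAS", 7: "MJJAS", 8: "MJJAS", 9: "MJJAS",
            10: "OND", 11: "OND", 12: "OND",
        }
    )

    def __post_init__(self) -> None:
        if sorted(self.month_to_season) != list(range(1, 13)):
            raise ConfigurationError("season definition must map each month 1-12 exactly once")

    @property
    def labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for m in range(1, 13):
            s = self.month_to_season[m]
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    def of_dates(self, dates) -> np.ndarray:
        """Season label for each date in a datetime-like sequence."""
        months = pd.DatetimeIndex(dates).month
        lut = np.empty(13, dtype=object)
        for m, s in self.month_to_season.items():
            lut[m] = s
        return lut[months.values]


DEFAULT_SEASONS = SeasonDefinition()
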