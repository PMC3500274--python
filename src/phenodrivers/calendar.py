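"""Composite calendar for 15-day NDVI records.

The satellite record provides 24 maximum-value composites per year. Composite
``i`` (1-based) is anchored to a fixed 365-day calendar: it starts on day
``1 + round((i - 1) * 365 / 24)`` and is dated by that start day. All month
membership decisions (the February--March winter-baseline window, the
December--March snow season, the 15th-of-month rule for climate windows) are
made on this calendar; leap days are ignored throughout.
"""

from __future__ import annotations

import numpy as np

COMPOSITES_PER_YEAR = 24
DAYS_PER_YEAR = 365
COMPOSITE_INTERVAL = DAYS_PER_YEAR / COMPOSITES_PER_YEAR  # ~15.2 days

#: start day-of-year of each composite, index 0 = composite 1
COMPOSITE_START_DAYS = np.array(
    [1 + round((i * DAYS_PER_YEAR) / COMPOSITES_PER_YEAR) for i in range(COMPOSITES_PER_YEAR)],
    dtype=int,
)

_MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_STARTS = np.concatenate([[1], 1 + np.cumsum(_MONTH_LENGTHS)[:-1]])  # day-of-year of the 1st


def composite_start_day(index: int) -> int:
    """Start day-of-year of a 1-based composite index."""
    if not 1 <= index <= COMPOSITES_PER_YEAR:
        raise ValueError(f"composite index must be in 1..{COMPOSITES_PER_YEAR}, got {index}")
    return int(COMPOSITE_START_DAYS[index - 1])


def doy_to_month_day(doy: float) -> tuple[int, int]:
    """Convert a day-of-year (1..365) to (month, day-of-month) on the 365-day calendar."""
    d = int(doy)
    if not 1 <= d <= DAYS_PER_YEAR:
        raise ValueError(f"day-of-year must be in 1..{DAYS_PER_YEAR}, got {doy}")
    month = int(np.searchsorted(_MONTH_STARTS, d, side="right"))
    return month, d - int(_MONTH_STARTS[month - 1]) + 1


def month_of_composite(index: int) -> int:
    """Calendar month (1..12) containing a composite's start day."""
    return doy_to_month_day(composite_start_day(index))[0]


#: 1-based composite indices whose start day falls in February--March
FEB_MAR_COMPOSITES = tuple(
    i for i in range(1, COMPOSITES_PER_YEAR + 1) if month_of_composite(i) in (2, 3)
)

#: 1-based composite indices in the December--March snow season
WINTER_COMPOSITES = tuple(
    i for i in range(1, COMPOSITES_PER_YEAR + 1) if month_of_composite(i) in (12, 1, 2, 3)
)


def first_composite_after(doy: float) -> int:
    """Smallest 1-based composite index whose start day is strictly after ``doy``.

    Used to map a continuous event date onto the composite grid: a rising
    threshold crossed at ``doy`` is first observed at this composite. Returns
    ``COMPOSITES_PER_YEAR + 1`` when the date falls after the last composite.
    """
    return int(np.searchsorted(COMPOSITE_START_DAYS, doy, side="right")) + 1
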