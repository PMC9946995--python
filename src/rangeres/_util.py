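"""Shared helpers: seeded substreams and the no-leap calendar."""

from __future__ import annotations

import zlib

import numpy as np

# Cumulative day counts of a 365-day (no-leap) calendar; month boundaries in
# scene dates are computed on this calendar so window tests are unambiguous.
_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_CUMDAYS = np.concatenate([[0], np.cumsum(_MONTH_DAYS)])
DAYS_PER_YEAR = 365


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a single root seed.

    Every random draw in the package flows from a root seed through one of
    these, so stages can be rerun independently with identical results.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]))


def date_value(year: int, month: int, day: int) -> float:
    """Fractional-year date of a calendar day (no-leap calendar).

    ``date_value(2016, 11, 1)`` is the instant 1 November 2016 begins; a scene
    dated 31 October falls strictly before it.
    """
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    if not 1 <= day <= _MONTH_DAYS[month - 1]:
        raise ValueError(f"day out of range for month {month}: {day}")
    doy = _CUMDAYS[month - 1] + (day - 1)
    return year + doy / DAYS_PER_YEAR
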