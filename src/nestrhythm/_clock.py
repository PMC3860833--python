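"""Clock and calendar helpers.

All timestamps in the package are seconds of local time since midnight of
the season anchor date (the first calendar day of the field season).
Intervals are half-open ``[start, end)`` and carry 1-s resolution.
"""

from __future__ import annotations

import datetime as dt

import numpy as np

SECONDS_PER_DAY = 86_400
SECONDS_PER_HOUR = 3_600


def parse_anchor(date_iso: str) -> dt.datetime:
    """Midnight (local) of the season anchor date."""
    return dt.datetime.fromisoformat(date_iso)


def seconds_to_iso(seconds, anchor: dt.datetime):
    """Vectorised conversion of season-seconds to ISO-8601 strings."""
    arr = np.asarray(seconds, dtype=np.int64)
    base = np.datetime64(anchor, "s")
    stamps = base + arr.astype("timedelta64[s]")
    return np.datetime_as_string(stamps, unit="s")


def iso_to_seconds(stamps, anchor: dt.datetime) -> np.ndarray:
    """Inverse of :func:`seconds_to_iso`."""
    base = np.datetime64(anchor, "s")
    arr = np.asarray(stamps, dtype="datetime64[s]")
    return (arr - base).astype(np.int64)


def clock_seconds(seconds) -> np.ndarray:
    """Seconds past local midnight for each timestamp."""
    return np.asarray(seconds) % SECONDS_PER_DAY


def parse_clock(hhmm: str) -> int:
    """``"21:30"`` -> seconds past midnight."""
    h, m = hhmm.split(":")
    return int(h) * 3600 + int(m) * 60


def format_clock(seconds: float) -> str:
    s = int(round(seconds)) % SECONDS_PER_DAY
    return f"{s // 3600:02d}:{(s % 3600) // 60:02d}"
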