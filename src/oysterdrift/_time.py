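"""Small time-coordinate helpers.

All timestamps in the package are UTC.  Internally the tracker works in
float seconds relative to a reference instant; these helpers convert
between that and ``numpy.datetime64`` / ``datetime`` objects.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np


def as_dt64(t) -> np.datetime64:
    """Coerce datetime/date/str/np.datetime64 to datetime64[ms]."""
    if isinstance(t, np.datetime64):
        return t.astype("datetime64[ms]")
    if isinstance(t, _dt.datetime):
        return np.datetime64(t.replace(tzinfo=None), "ms")
    if isinstance(t, _dt.date):
        return np.datetime64(t.isoformat(), "ms")
    return np.datetime64(t, "ms")


def seconds_since(t, ref: np.datetime64) -> float:
    """Seconds from ``ref`` to ``t`` (float, may be negative)."""
    return float((as_dt64(t) - as_dt64(ref)) / np.timedelta64(1, "s"))


def offset_seconds(ref: np.datetime64, seconds) -> np.datetime64:
    """``ref + seconds`` as datetime64[ms] (vectorized over seconds)."""
    ms = np.round(np.asarray(seconds, dtype=float) * 1000.0).astype("timedelta64[ms]")
    return as_dt64(ref) + ms
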