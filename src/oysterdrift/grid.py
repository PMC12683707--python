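"""Regular lon/lat grid specification.

All gridded objects in the package (velocity snapshots, dispersal
footprints) live on a regular WGS84 lon/lat grid described by a
:class:`GridSpec`.  ``lon_min``..``lat_max`` are *outer edges*; the grid is
divided into ``nx`` x ``ny`` cells whose centers carry the field values.
Cell membership is half-open, ``[west, east) x [south, north)``, so every
point strictly inside the bounds belongs to exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidGridError


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid: outer bounds, cell counts, snapshot cadence.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max
        Outer edges of the domain in decimal degrees (WGS84).
    nx, ny
        Number of cells along longitude and latitude (>= 2 each).
    snapshot_interval
        Seconds between stored velocity snapshots (integer seconds, > 0).
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    nx: int
    ny: int
    snapshot_interval: int = 3600

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise InvalidGridError(
                f"degenerate bounds: lon [{self.lon_min}, {self.lon_max}], "
                f"lat [{self.lat_min}, {self.lat_max}]"
            )
        if self.nx < 2 or self.ny < 2:
            raise InvalidGridError(f"need nx, ny >= 2, got {self.nx} x {self.ny}")
        si = self.snapshot_interval
        if si <= 0 or int(si) != si:
            raise InvalidGridError(f"snapshot_interval must be a positive whole number of seconds, got {si}")

    @property
    def dlon(self) -> float:
        return (self.lon_max - self.lon_min) / self.nx

    @property
    def dlat(self) -> float:
        return (self.lat_max - self.lat_min) / self.ny

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.nx) + 0.5) * self.dlon

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.ny) + 0.5) * self.dlat

    def contains(self, lon, lat) -> np.ndarray:
        """Vectorized bounds check against the outer edges."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Half-open cell membership: indices (i along lon, j along lat).

        Points on the eastern/northern outer edge are folded into the last
        cell so the closed domain maps onto valid indices.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        i = np.floor((lon - self.lon_min) / self.dlon).astype(np.int64)
        j = np.floor((lat - self.lat_min) / self.dlat).astype(np.int64)
        i = np.clip(i, 0, self.nx - 1)
        j = np.clip(j, 0, self.ny - 1)
        return i, j
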