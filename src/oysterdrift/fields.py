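"""Gridded velocity time series and space-time interpolation.

A :class:`VelocityFieldSeries` holds u, v snapshots (m/s) on a regular
lon/lat grid at evenly spaced instants, one series per drift layer
(``surface`` or ``depth_averaged``).  Land cells carry zero velocity and
``water=False``.

Interpolation is bilinear between the four surrounding cell centers and
linear in time between bracketing snapshots.  Land cells contribute their
(zero) velocity with full weight — a particle approaching the coast is
decelerated rather than abruptly stopped, and the land-interaction rule in
the tracker decides what happens when a step would actually end on land.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._time import as_dt64, seconds_since
from .errors import OutOfDomainError, ValidationError
from .grid import GridSpec

LAYERS = ("surface", "depth_averaged")


@dataclass
class VelocityFieldSeries:
    """u, v on a regular grid x time, with a land mask.

    Attributes
    ----------
    grid : GridSpec
    times : np.ndarray of datetime64, shape (nt,)
        Strictly increasing, evenly spaced snapshot instants.
    u, v : np.ndarray, shape (nt, ny, nx)
        Eastward / northward velocity in m/s; exactly zero on land cells.
    water : np.ndarray of bool, shape (ny, nx)
        True on water cells.
    layer_tag : str
        ``surface`` or ``depth_averaged``.
    """

    grid: GridSpec
    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    water: np.ndarray
    layer_tag: str = "depth_averaged"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times).astype("datetime64[ms]")
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.water = np.asarray(self.water, dtype=bool)
        nt = self.times.shape[0]
        ny, nx = self.grid.ny, self.grid.nx
        if self.u.shape != (nt, ny, nx) or self.v.shape != (nt, ny, nx):
            raise ValidationError(
                f"velocity shape {self.u.shape} does not match (nt={nt}, ny={ny}, nx={nx})"
            )
        if self.water.shape != (ny, nx):
            raise ValidationError(f"mask shape {self.water.shape} != ({ny}, {nx})")
        if self.layer_tag not in LAYERS:
            raise ValidationError(f"layer_tag must be one of {LAYERS}, got {self.layer_tag!r}")
        if nt >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= np.timedelta64(0, "ms")):
                raise ValidationError("snapshot times must be strictly increasing")
            if np.any(dt != dt[0]):
                raise ValidationError("snapshot times must be evenly spaced")
        if not np.all(np.isfinite(self.u[:, self.water])) or not np.all(
            np.isfinite(self.v[:, self.water])
        ):
            raise ValidationError("non-finite velocity on water cells")

    # -- time coordinate ------------------------------------------------

    @property
    def t0(self) -> np.datetime64:
        return self.times[0]

    @property
    def snapshot_seconds(self) -> float:
        if len(self.times) < 2:
            return float(self.grid.snapshot_interval)
        return float((self.times[1] - self.times[0]) / np.timedelta64(1, "s"))

    @property
    def duration_seconds(self) -> float:
        return float((self.times[-1] - self.times[0]) / np.timedelta64(1, "s"))

    # -- interpolation --------------------------------------------------

    def interp(self, lon, lat, tsec) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized bilinear-in-space, linear-in-time velocity.

        ``tsec`` is float seconds since ``self.t0`` (broadcastable with
        lon/lat).  Coordinates are clamped to the grid — callers must do
        their own bounds policing (``velocity_at`` raises, the tracker
        flags exits).
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        tsec = np.asarray(tsec, dtype=float)
        g = self.grid

        dt = self.snapshot_seconds
        nt = len(self.times)
        ft = np.clip(tsec / dt, 0.0, nt - 1.0)
        it = np.minimum(ft.astype(np.int64), max(nt - 2, 0))
        wt = np.clip(ft - it, 0.0, 1.0)

        fx = np.clip((lon - g.lon_centers[0]) / g.dlon, 0.0, g.nx - 1.0)
        fy = np.clip((lat - g.lat_centers[0]) / g.dlat, 0.0, g.ny - 1.0)
        i0 = np.minimum(fx.astype(np.int64), g.nx - 2)
        j0 = np.minimum(fy.astype(np.int64), g.ny - 2)
        wx = np.clip(fx - i0, 0.0, 1.0)
        wy = np.clip(fy - j0, 0.0, 1.0)
        # snap to grid nodes so queries at cell centers return stored values
        wx = np.where(wx < 1e-9, 0.0, np.where(wx > 1 - 1e-9, 1.0, wx))
        wy = np.where(wy < 1e-9, 0.0, np.where(wy > 1 - 1e-9, 1.0, wy))
        wt = np.where(wt < 1e-9, 0.0, np.where(wt > 1 - 1e-9, 1.0, wt))

        it1 = np.minimum(it + 1, nt - 1)
        out = []
        for comp in (self.u, self.v):
            vals = 0.0
            for (jj, ii, w_sp) in (
                (j0, i0, (1 - wx) * (1 - wy)),
                (j0, i0 + 1, wx * (1 - wy)),
                (j0 + 1, i0, (1 - wx) * wy),
                (j0 + 1, i0 + 1, wx * wy),
            ):
                vals = vals + w_sp * (
                    (1 - wt) * comp[it, jj, ii] + wt * comp[it1, jj, ii]
                )
            out.append(vals)
        return out[0], out[1]


def velocity_at(field: VelocityFieldSeries, lon: float, lat: float, t) -> tuple[float, float]:
    """Interpolated (u, v) at a point and instant; raises out of domain."""
    g = field.grid
    if not (g.lon_min <= lon <= g.lon_max and g.lat_min <= lat <= g.lat_max):
        raise OutOfDomainError(f"position ({lon}, {lat}) outside grid bounds")
    tsec = seconds_since(t, field.t0)
    if tsec < 0 or tsec > field.duration_seconds:
        raise OutOfDomainError(f"time {as_dt64(t)} outside [{field.times[0]}, {field.times[-1]}]")
    u, v = field.interp(lon, lat, tsec)
    return float(u), float(v)
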