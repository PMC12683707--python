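"""Synthetic German Bight-like environment for offline pipeline runs.

The study region's hydrodynamics are emulated, not solved: currents are a
tidal oscillation (M2 period, optionally elliptic) plus a steerable steady
wind-driven residual plus white noise; temperature is a seasonal sinusoid
whose defaults cross the 15 degC spawning threshold in mid-June, as the
southern North Sea does.  Geometry is a simplified topology of the real
study area — a southern source MPA (Borkum Reef Ground analog) holding
three restoration sites at the published coordinates, a transit gap, and a
north-eastern sink MPA (Sylt Outer Reef analog).

Everything is seeded and bit-reproducible; these generators define the
study conditions for all tests and property checks.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import box

from ._time import as_dt64, seconds_since
from .detections import DETECTION_COLUMNS, DetectionSet, DispersalFootprint
from .errors import InsufficientSpaceError, InvalidWindowError, ValidationError
from .fields import VelocityFieldSeries
from .grid import GridSpec
from .pld import TemperatureSeries
from .regions import PointSite, RegionSet

import pandas as pd

M2_PERIOD_S = 44_712.0  # principal lunar semidiurnal tide


@dataclass(frozen=True)
class FlowRecipe:
    """Tidal + residual + noise current recipe.

    Velocities (m/s):
    ``u = residual_u + tidal_amplitude_u * sin(2*pi*t/period + phase_u) + noise``
    and analogously for v.  The v-phase defaults to the u-phase + 90 deg so
    the default tide traces an ellipse rather than a rectilinear
    oscillation; set ``tidal_phase_v`` explicitly for other polarizations.
    Noise is white in space and time with standard deviation ``noise_sd``.
    """

    tidal_amplitude_u: float = 0.5
    tidal_amplitude_v: float = 0.25
    tidal_period: float = M2_PERIOD_S
    tidal_phase: float = 0.0
    tidal_phase_v: Optional[float] = None
    residual_u: float = 0.0
    residual_v: float = 0.0
    noise_sd: float = 0.0
    land_polygons: Sequence = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tidal_amplitude_u < 0 or self.tidal_amplitude_v < 0:
            raise ValidationError("tidal amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.tidal_period <= 0:
            raise ValidationError("tidal_period must be positive")

    @property
    def phase_v(self) -> float:
        return self.tidal_phase + np.pi / 2 if self.tidal_phase_v is None else self.tidal_phase_v


@dataclass(frozen=True)
class TemperatureRecipe:
    """Seasonal sinusoid + anomaly + noise for daily mean temperature.

    Defaults emulate the German Bight: annual mean ~11 degC, seasonal
    amplitude 7 degC peaking in early August (day 220), which crosses the
    15 degC spawning threshold around mid-June on the way up.
    """

    mean_annual: float = 11.0
    amplitude: float = 7.0
    peak_day_of_year: int = 220
    anomaly: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def make_flow_field(
    grid: GridSpec, recipe: FlowRecipe, t_start, t_end, layer_tag: str = "surface"
) -> VelocityFieldSeries:
    """Generate a velocity series at the grid's snapshot interval.

    Cells whose center lies inside a land polygon get u = v = 0 and are
    masked as land.  Deterministic given ``recipe.seed``.
    """
    t0 = as_dt64(t_start)
    total = seconds_since(t_end, t0)
    if total <= 0:
        raise InvalidWindowError(f"t_end {t_end} not after t_start {t_start}")

    si = grid.snapshot_interval
    nt = int(np.floor(total / si)) + 1
    times = t0 + (np.arange(nt) * si * 1000).astype("timedelta64[ms]")
    tsec = np.arange(nt) * float(si)

    omega = 2 * np.pi / recipe.tidal_period
    u_t = recipe.residual_u + recipe.tidal_amplitude_u * np.sin(omega * tsec + recipe.tidal_phase)
    v_t = recipe.residual_v + recipe.tidal_amplitude_v * np.sin(omega * tsec + recipe.phase_v)

    shape = (nt, grid.ny, grid.nx)
    u = np.broadcast_to(u_t[:, None, None], shape).copy()
    v = np.broadcast_to(v_t[:, None, None], shape).copy()
    if recipe.noise_sd > 0:
        rng = np.random.default_rng(recipe.seed)
        u += rng.normal(0.0, recipe.noise_sd, shape)
        v += rng.normal(0.0, recipe.noise_sd, shape)

    water = np.ones((grid.ny, grid.nx), dtype=bool)
    if recipe.land_polygons:
        lon_c, lat_c = np.meshgrid(grid.lon_centers, grid.lat_centers)
        pts = shapely.points(lon_c.ravel(), lat_c.ravel())
        for poly in recipe.land_polygons:
            water &= ~shapely.intersects(poly, pts).reshape(grid.ny, grid.nx)
        u[:, ~water] = 0.0
        v[:, ~water] = 0.0

    return VelocityFieldSeries(grid=grid, times=times, u=u, v=v, water=water, layer_tag=layer_tag)


def make_temperature_series(
    recipe: TemperatureRecipe, t_start, t_end, layer_tag: str = "surface"
) -> TemperatureSeries:
    """Daily mean temperature for [t_start, t_end] inclusive; seeded."""
    d0 = np.datetime64(as_dt64(t_start), "D")
    d1 = np.datetime64(as_dt64(t_end), "D")
    if d1 < d0:
        raise InvalidWindowError(f"t_end {t_end} before t_start {t_start}")
    n = int((d1 - d0) / np.timedelta64(1, "D")) + 1
    dates = d0 + np.arange(n).astype("timedelta64[D]")
    year_start = dates.astype("datetime64[Y]").astype("datetime64[D]")
    doy = (dates - year_start) / np.timedelta64(1, "D") + 1
    values = (
        recipe.mean_annual
        + recipe.amplitude * np.cos(2 * np.pi * (doy - recipe.peak_day_of_year) / 365.25)
        + recipe.anomaly
    )
    if recipe.noise_sd > 0:
        rng = np.random.default_rng(recipe.seed)
        values = values + rng.normal(0.0, recipe.noise_sd, n)
    return TemperatureSeries(start_date=d0, values=values, layer_tag=layer_tag)


# Published restoration-site coordinates (lon, lat)
SITE_COORDS = {
    "BRG-DE": (6.2802, 53.9166),
    "BRG-NL": (6.3490, 53.7017),
    "Gemini-NL": (6.0777, 54.0107),
}


def make_study_geometry(
    source_mpa_bounds=(6.0, 53.75, 6.6, 54.05),
    sink_mpa_bounds=(6.9, 54.45, 7.7, 54.95),
    transit_bounds=(6.2, 54.05, 7.3, 54.45),
    site_coords: dict = None,
    site_radius_m: float = 1000.0,
) -> RegionSet:
    """Two disjoint MPA rectangles separated by a transit gap, plus sites.

    The source MPA sits to the southwest with the three restoration sites
    inside or just south of it; the sink MPA lies to the northeast, so a
    steady southwest-to-northeast residual connects them.  Bounds are
    (lon_min, lat_min, lon_max, lat_max).
    """
    coords = dict(SITE_COORDS if site_coords is None else site_coords)
    polygons = {
        "source-MPA": box(*source_mpa_bounds),
        "sink-MPA": box(*sink_mpa_bounds),
        "transit": box(*transit_bounds),
    }
    kinds = {"source-MPA": "mpa", "sink-MPA": "mpa", "transit": "transit"}
    sites = {
        name: PointSite(lon=lon, lat=lat, radius_m=site_radius_m)
        for name, (lon, lat) in coords.items()
    }
    return RegionSet(polygons=polygons, sites=sites, kinds=kinds)


def make_detections(
    footprint: DispersalFootprint,
    n_inside: int,
    n_outside: int,
    seed: int = 0,
    date: _dt.date = _dt.date(2022, 6, 28),
) -> DetectionSet:
    """Detection stations sampled inside/outside the dispersal footprint.

    ``n_inside`` stations land uniformly in occupied water cells and
    ``n_outside`` in unoccupied water cells (without replacement for the
    latter), each jittered within its cell, all with detected=True.  The
    downstream overlap count is therefore n_inside of
    (n_inside + n_outside) by construction.
    """
    rng = np.random.default_rng(seed)
    g = footprint.grid
    occ = footprint.occupancy("union") & footprint.water
    unocc = ~footprint.occupancy("union") & footprint.water
    occ_idx = np.flatnonzero(occ.ravel())
    unocc_idx = np.flatnonzero(unocc.ravel())

    if n_inside > 0 and occ_idx.size == 0:
        raise ValidationError("footprint is empty but n_inside > 0")
    if n_outside > unocc_idx.size:
        raise InsufficientSpaceError(
            f"requested {n_outside} outside stations but only {unocc_idx.size} "
            "unoccupied water cells available"
        )

    chosen_in = rng.choice(occ_idx, size=n_inside, replace=True) if n_inside else np.array([], int)
    chosen_out = (
        rng.choice(unocc_idx, size=n_outside, replace=False) if n_outside else np.array([], int)
    )
    flat = np.concatenate([chosen_in, chosen_out]).astype(np.int64)
    j, i = np.divmod(flat, g.nx)
    # jitter keeps each station strictly inside its (half-open) cell
    lon = g.lon_min + (i + 0.2 + 0.6 * rng.random(flat.size)) * g.dlon
    lat = g.lat_min + (j + 0.2 + 0.6 * rng.random(flat.size)) * g.dlat

    n = flat.size
    methods = np.where(np.arange(n) % 2 == 0, "meroplankton", "eDNA")
    table = pd.DataFrame(
        {
            "station_id": [f"ST{k + 1:03d}" for k in range(n)],
            "lon": lon,
            "lat": lat,
            "date": [date] * n,
            "method": methods,
            "detected": True,
        },
        columns=DETECTION_COLUMNS,
    )
    return DetectionSet(table)
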