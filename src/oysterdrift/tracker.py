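"""Lagrangian advection of passive larvae through a gridded velocity field.

Particles represent individual oyster larvae drifting passively in a single
horizontal layer (surface or depth-averaged currents).  Positions evolve by

    dlon/dt = u / (R cos(lat) * pi/180),   dlat/dt = v / (R * pi/180)

integrated with fixed-step 4th-order Runge-Kutta (default step 465 s).
Sub-steps are truncated so each particle lands exactly on its hourly output
marks, on its competency-start instant and on its stop time; recorded
samples therefore carry exact nominal timestamps.

Land interaction is stall-in-place: a step whose endpoint falls on a land
cell is discarded and the particle waits (tidal reversal may free it
later).  A step leaving the open boundary freezes the particle at its last
in-domain position with status ``exited``.  Together with ``settled`` this
keeps the conservation identity exact: every released particle is at all
times in exactly one of {drifting, competent, settled, stalled, exited}
(``competent`` is the drifting sub-state inside the settlement-competency
window of the extended scenario).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field as _field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from ._time import as_dt64, offset_seconds, seconds_since
from .errors import (
    ConfigurationError,
    CorruptFieldError,
    NoWaterError,
    OutOfDomainError,
    ValidationError,
)
from .fields import VelocityFieldSeries
from .pld import PLDParameters, TemperatureSeries, settlement_window

R_EARTH_M = 6_371_000.0
DEG_PER_M = 180.0 / (np.pi * R_EARTH_M)  # degrees latitude per meter

STATUS_NAMES = ("drifting", "competent", "settled", "stalled", "exited")
_DRIFTING, _COMPETENT, _SETTLED, _STALLED, _EXITED = range(5)


@dataclass(frozen=True)
class ReleaseDisk:
    """1-km-style release disk around a restoration site."""

    lon: float
    lat: float
    radius_m: float = 1000.0

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValidationError("disk radius must be positive")


@dataclass(frozen=True)
class ReleaseSchedule:
    """Hourly particle releases from a disk or polygon source.

    Releases are placed on the hour, start-inclusive and end-exclusive:
    200/h over the 61-day spawning window June 15 - Aug 15 gives the
    292,800 particles per site of the seasonal experiments.
    """

    source_name: str
    geometry: Union[ReleaseDisk, BaseGeometry]
    rate_per_hour: int
    start: _dt.datetime
    end: _dt.datetime
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_per_hour < 1:
            raise ValidationError("rate_per_hour must be >= 1")
        if as_dt64(self.start) >= as_dt64(self.end):
            raise ValidationError("release window must have start < end")


@dataclass(frozen=True)
class ScenarioConfig:
    """Drift-layer / competency scenario and integration settings."""

    layer: str = "surface"
    pld_scenario: str = "strict"
    integration_step: float = 465.0
    output_interval: float = 3600.0
    hard_stop: Optional[_dt.datetime] = None

    def __post_init__(self) -> None:
        if self.layer not in ("surface", "depth_averaged"):
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.pld_scenario not in ("strict", "extended"):
            raise ValidationError(f"unknown pld_scenario {self.pld_scenario!r}")
        if self.integration_step <= 0:
            raise ValidationError("integration_step must be positive")
        if self.output_interval < self.integration_step:
            raise ValidationError("output_interval must be >= integration_step")


@dataclass
class TrajectorySet:
    """Per-particle summary plus recorded position samples.

    ``particles`` columns: particle_id, source, release_time, release_lon,
    release_lat, competency_start, competency_end, settlement_lon,
    settlement_lat, status.

    ``samples`` columns: particle_id, source, release_time, time, lon, lat,
    status — one row per recorded output instant, time-ordered per
    particle; ``status`` is ``drift`` before competency starts and
    ``competent`` from the competency-start sample onward.
    """

    particles: pd.DataFrame
    samples: pd.DataFrame
    scenario: ScenarioConfig = _field(default_factory=ScenarioConfig)

    @property
    def status_counts(self) -> dict:
        c = self.particles["status"].value_counts().to_dict()
        return {name: int(c.get(name, 0)) for name in STATUS_NAMES}

    @property
    def n_released(self) -> int:
        return len(self.particles)

    def for_source(self, source: str) -> "TrajectorySet":
        p = self.particles[self.particles["source"] == source]
        s = self.samples[self.samples["source"] == source]
        return TrajectorySet(p.reset_index(drop=True), s.reset_index(drop=True), self.scenario)


# ---------------------------------------------------------------------------
# Release sampling


def count_released(schedule: ReleaseSchedule) -> int:
    """Total particles for a schedule: rate x number of hourly release instants.

    Instants are ``start + k*3600 s`` for every k with instant < end.
    """
    total_sec = seconds_since(schedule.end, as_dt64(schedule.start))
    n_instants = int(np.ceil(total_sec / 3600.0 - 1e-12))
    return schedule.rate_per_hour * n_instants


def release_instants(schedule: ReleaseSchedule) -> np.ndarray:
    n = count_released(schedule) // schedule.rate_per_hour
    return as_dt64(schedule.start) + (np.arange(n) * 3600_000).astype("timedelta64[ms]")


def sample_release_positions(
    schedule: ReleaseSchedule,
    n: Optional[int] = None,
    water_test=None,
    rng: Optional[np.random.Generator] = None,
):
    """Draw ``n`` release positions uniformly over the source geometry.

    Disk sources use sqrt-uniform radius and uniform azimuth (uniform by
    area); polygon sources use rejection sampling in the bounding box.
    Draws landing on land (per ``water_test(lon, lat) -> bool array``) are
    redrawn; a geometry with no water raises :class:`NoWaterError`.
    """
    if n is None:
        n = count_released(schedule)
    if rng is None:
        rng = np.random.default_rng(schedule.seed)
    geom = schedule.geometry

    def draw(m: int):
        if isinstance(geom, ReleaseDisk):
            r = geom.radius_m * np.sqrt(rng.random(m))
            theta = rng.random(m) * 2 * np.pi
            lat = geom.lat + r * np.cos(theta) * DEG_PER_M
            lon = geom.lon + r * np.sin(theta) * DEG_PER_M / np.cos(np.radians(geom.lat))
            return lon, lat
        minx, miny, maxx, maxy = geom.bounds
        lon = np.empty(m)
        lat = np.empty(m)
        got = 0
        while got < m:
            cx = rng.uniform(minx, maxx, m - got)
            cy = rng.uniform(miny, maxy, m - got)
            ok = shapely.intersects(geom, shapely.points(cx, cy))
            k = int(ok.sum())
            lon[got : got + k] = cx[ok]
            lat[got : got + k] = cy[ok]
            got += k
        return lon, lat

    if n == 0:
        return np.empty(0), np.empty(0)
    lon, lat = draw(n)
    if water_test is not None:
        for _ in range(100):
            wet = np.asarray(water_test(lon, lat), dtype=bool)
            if wet.all():
                break
            m = int((~wet).sum())
            lon[~wet], lat[~wet] = draw(m)
        else:
            raise NoWaterError(
                f"could not place {int((~wet).sum())} release positions on water "
                f"for source {schedule.source_name!r}"
            )
    return lon, lat


# ---------------------------------------------------------------------------
# Advection


def _deriv(field: VelocityFieldSeries, lon, lat, tsec):
    """RHS of the advection ODE in degrees/second."""
    u, v = field.interp(lon, lat, tsec)
    dlon = u * DEG_PER_M / np.cos(np.radians(lat))
    dlat = v * DEG_PER_M
    return dlon, dlat


def _rk4(field: VelocityFieldSeries, lon, lat, tsec, dt):
    """One vectorized RK4 step; dt may be a per-particle array."""
    k1x, k1y = _deriv(field, lon, lat, tsec)
    k2x, k2y = _deriv(field, lon + 0.5 * dt * k1x, lat + 0.5 * dt * k1y, tsec + 0.5 * dt)
    k3x, k3y = _deriv(field, lon + 0.5 * dt * k2x, lat + 0.5 * dt * k2y, tsec + 0.5 * dt)
    k4x, k4y = _deriv(field, lon + dt * k3x, lat + dt * k3y, tsec + dt)
    new_lon = lon + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
    new_lat = lat + dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
    return new_lon, new_lat


def _euler(field: VelocityFieldSeries, lon, lat, tsec, dt):
    k1x, k1y = _deriv(field, lon, lat, tsec)
    return lon + dt * k1x, lat + dt * k1y


_SCHEMES = {"rk4": _rk4, "euler": _euler}


def step(position, t, field: VelocityFieldSeries, dt: float, scheme: str = "rk4"):
    """Advance one particle by ``dt`` seconds; scalar convenience wrapper.

    Returns the new (lon, lat).  If the proposed endpoint is on land or
    outside the domain the particle keeps its current position (the
    ensemble runner additionally flags it stalled / exited).
    """
    lon, lat = position
    tsec = seconds_since(t, field.t0)
    u, v = field.interp(lon, lat, tsec)
    if not (np.isfinite(u) and np.isfinite(v)):
        raise CorruptFieldError(f"non-finite velocity at ({lon}, {lat})")
    new_lon, new_lat = _SCHEMES[scheme](field, np.float64(lon), np.float64(lat), tsec, dt)
    g = field.grid
    if not bool(g.contains(new_lon, new_lat)):
        return (lon, lat)
    i, j = g.cell_index(new_lon, new_lat)
    if not bool(field.water[j, i]):
        return (lon, lat)
    return (float(new_lon), float(new_lat))


def advect(position, t_start, t_end, field: VelocityFieldSeries, dt: float = 465.0, scheme: str = "rk4"):
    """Advect a single particle from t_start to t_end, truncating the last step."""
    t0 = seconds_since(t_start, field.t0)
    t1 = seconds_since(t_end, field.t0)
    if t1 < t0:
        raise OutOfDomainError("t_end before t_start")
    pos = position
    t = t0
    while t < t1 - 1e-9:
        h = min(dt, t1 - t)
        pos = step(pos, offset_seconds(field.t0, t), field, h, scheme)
        t += h
    return pos


# ---------------------------------------------------------------------------
# Ensemble runner


def run_ensemble(
    field: VelocityFieldSeries,
    schedules: Sequence[ReleaseSchedule],
    temps: TemperatureSeries,
    scenario: ScenarioConfig,
    pld_params: PLDParameters = PLDParameters(),
    scheme: str = "rk4",
) -> TrajectorySet:
    """Release, advect and settle a particle ensemble; fully seeded.

    In the strict scenario each particle stops and records its settlement
    position the instant its pelagic stage completes.  In the extended
    scenario it records that same position, then keeps drifting (and being
    sampled) through the 14-day competency window.  ``hard_stop`` and the
    end of the velocity series truncate all drift.
    """
    if field.layer_tag != scenario.layer:
        raise ConfigurationError(
            f"field layer {field.layer_tag!r} != scenario layer {scenario.layer!r}"
        )
    if temps.layer_tag != scenario.layer:
        raise ConfigurationError(
            f"temperature layer {temps.layer_tag!r} != scenario layer {scenario.layer!r}"
        )

    ext_days = pld_params.extension_days if scenario.pld_scenario == "extended" else 0.0
    eff_params = PLDParameters(
        coefficient=pld_params.coefficient,
        exponent=pld_params.exponent,
        extension_days=ext_days,
        mode=pld_params.mode,
    )

    t0 = field.t0
    field_end = field.duration_seconds
    hard = (
        min(seconds_since(scenario.hard_stop, t0), field_end)
        if scenario.hard_stop is not None
        else field_end
    )

    def water_test(lon, lat):
        inb = field.grid.contains(lon, lat)
        i, j = field.grid.cell_index(lon, lat)
        return inb & field.water[j, i]

    # --- assemble the ensemble ------------------------------------------
    ids, srcs, rel_t, lon0, lat0, comp_s, comp_e = [], [], [], [], [], [], []
    next_id = 0
    for sched in schedules:
        instants = release_instants(sched)
        n_total = len(instants) * sched.rate_per_hour
        plon, plat = sample_release_positions(sched, n_total, water_test=water_test)
        # one settlement window per release instant (shared regional temperature)
        windows = [settlement_window(t, temps, eff_params) for t in instants]
        cs = np.repeat([seconds_since(w[0], t0) for w in windows], sched.rate_per_hour)
        ce = np.repeat([seconds_since(w[1], t0) for w in windows], sched.rate_per_hour)
        rt = np.repeat([seconds_since(t, t0) for t in instants], sched.rate_per_hour)
        ids.append(np.arange(next_id, next_id + n_total))
        next_id += n_total
        srcs.append(np.full(n_total, sched.source_name, dtype=object))
        rel_t.append(rt)
        lon0.append(plon)
        lat0.append(plat)
        comp_s.append(cs)
        comp_e.append(ce)

    pid = np.concatenate(ids)
    source = np.concatenate(srcs)
    release_sec = np.concatenate(rel_t)
    lon = np.concatenate(lon0).astype(float)
    lat = np.concatenate(lat0).astype(float)
    comp_start = np.concatenate(comp_s)
    comp_end = np.concatenate(comp_e)
    n = len(pid)

    release_lon = lon.copy()
    release_lat = lat.copy()
    stop = np.minimum(comp_end, hard)
    t = release_sec.copy()
    status = np.full(n, _DRIFTING, dtype=np.int8)
    settle_lon = np.full(n, np.nan)
    settle_lat = np.full(n, np.nan)

    rec_pid, rec_t, rec_lon, rec_lat, rec_ph = [], [], [], [], []

    def record(sel_idx):
        rec_pid.append(pid[sel_idx])
        rec_t.append(t[sel_idx])
        rec_lon.append(lon[sel_idx])
        rec_lat.append(lat[sel_idx])
        rec_ph.append((t[sel_idx] >= comp_start[sel_idx] - 1e-6).astype(np.int8))

    # particles released after hard stop never drift
    dead_on_arrival = release_sec >= hard - 1e-9
    record(np.flatnonzero(~dead_on_arrival))  # initial positions
    record(np.flatnonzero(dead_on_arrival))

    oi = float(scenario.output_interval)
    h_max = float(scenario.integration_step)
    g = field.grid

    active = (~dead_on_arrival) & (t < stop - 1e-9)
    idx = np.flatnonzero(active)
    while idx.size:
        tc = t[idx]
        # candidate next times: full step, next output mark, competency start, stop
        k = np.floor((tc - release_sec[idx]) / oi + 1e-9) + 1
        mark = release_sec[idx] + k * oi
        t_new = np.minimum(tc + h_max, mark)
        before_comp = tc < comp_start[idx] - 1e-9
        t_new = np.where(before_comp, np.minimum(t_new, comp_start[idx]), t_new)
        t_new = np.minimum(t_new, stop[idx])
        h = t_new - tc

        new_lon, new_lat = _rk4(field, lon[idx], lat[idx], tc, h) if scheme == "rk4" else _euler(
            field, lon[idx], lat[idx], tc, h
        )
        inb = g.contains(new_lon, new_lat)
        ci, cj = g.cell_index(new_lon, new_lat)
        wet = field.water[cj, ci] & inb

        exited_now = ~inb
        stalled_now = inb & ~wet
        moved = wet

        moved_idx = idx[moved]
        lon[moved_idx] = new_lon[moved]
        lat[moved_idx] = new_lat[moved]

        t[idx[~exited_now]] = t_new[~exited_now]
        status[idx[exited_now]] = _EXITED
        status[idx[stalled_now]] = _STALLED
        in_win_m = t[moved_idx] >= comp_start[moved_idx] - 1e-6
        status[moved_idx] = np.where(in_win_m, _COMPETENT, _DRIFTING)

        alive = idx[~exited_now]

        # settlement-position capture at competency start
        hit_comp = alive[np.abs(t[alive] - comp_start[alive]) < 1e-6]
        fresh = hit_comp[~np.isfinite(settle_lon[hit_comp])]
        settle_lon[fresh] = lon[fresh]
        settle_lat[fresh] = lat[fresh]

        # record samples at output marks / competency start / stop
        at_mark_phase = (t[alive] - release_sec[alive]) % oi
        at_mark = (at_mark_phase < 1e-6) | (at_mark_phase > oi - 1e-6)
        at_comp = np.abs(t[alive] - comp_start[alive]) < 1e-6
        at_stop = t[alive] >= stop[alive] - 1e-9
        record(alive[at_mark | at_comp | at_stop])

        done = t >= stop - 1e-9
        finished = alive[done[alive]]
        reached_end = finished[np.abs(stop[finished] - comp_end[finished]) < 1e-6]
        # reaching the end of the competency window (strict: == its start) settles
        settled_mask = np.isfinite(settle_lon[reached_end])
        status[reached_end[settled_mask]] = _SETTLED

        active[idx[exited_now]] = False
        active[finished] = False
        idx = np.flatnonzero(active)

    particles = pd.DataFrame(
        {
            "particle_id": pid,
            "source": source,
            "release_time": offset_seconds(t0, release_sec),
            "release_lon": release_lon,
            "release_lat": release_lat,
            "competency_start": offset_seconds(t0, comp_start),
            "competency_end": offset_seconds(t0, comp_end),
            "settlement_lon": settle_lon,
            "settlement_lat": settle_lat,
            "status": np.array(STATUS_NAMES, dtype=object)[status],
        }
    )

    samples = pd.DataFrame(
        {
            "particle_id": np.concatenate(rec_pid) if rec_pid else np.array([], dtype=np.int64),
            "time": offset_seconds(t0, np.concatenate(rec_t) if rec_t else np.array([])),
            "lon": np.concatenate(rec_lon) if rec_lon else np.array([]),
            "lat": np.concatenate(rec_lat) if rec_lat else np.array([]),
            "status": np.where(
                np.concatenate(rec_ph) if rec_ph else np.array([], dtype=np.int8),
                "competent",
                "drift",
            ),
        }
    )
    samples = samples.merge(
        particles[["particle_id", "source", "release_time"]], on="particle_id", how="left"
    )
    samples = samples.sort_values(["particle_id", "time"], kind="mergesort").reset_index(drop=True)
    samples = samples[["particle_id", "source", "release_time", "time", "lon", "lat", "status"]]

    return TrajectorySet(particles=particles, samples=samples, scenario=scenario)
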