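"""Release sampling, advection oracles and ensemble behavior."""

import datetime as dt

import numpy as np
import pytest
from shapely.geometry import box

from oysterdrift import (
    FlowRecipe,
    GridSpec,
    PLDParameters,
    ReleaseDisk,
    ReleaseSchedule,
    ScenarioConfig,
    TemperatureSeries,
    VelocityFieldSeries,
    advect,
    count_released,
    make_flow_field,
    run_ensemble,
    sample_release_positions,
    step,
    velocity_at,
)
from oysterdrift.connectivity import _haversine_m
from oysterdrift.errors import ConfigurationError, OutOfDomainError
from oysterdrift.tracker import DEG_PER_M

T0 = dt.datetime(2022, 6, 15)
GRID = GridSpec(5.0, 9.0, 53.0, 55.5, nx=40, ny=25, snapshot_interval=3600)


def _uniform_field(u=0.0, v=0.0, days=20, layer="surface", grid=GRID):
    recipe = FlowRecipe(
        tidal_amplitude_u=0, tidal_amplitude_v=0, residual_u=u, residual_v=v, noise_sd=0
    )
    return make_flow_field(grid, recipe, T0, T0 + dt.timedelta(days=days), layer_tag=layer)


def _const_temps(T=15.0, days=60, layer="surface"):
    return TemperatureSeries(dt.date(2022, 6, 15), np.full(days, float(T)), layer_tag=layer)


# ---------------------------------------------------------------------------
# release schedules


@pytest.mark.parametrize(
    "rate, days, expected",
    [(200, 61, 292_800), (500, 61, 732_000), (200, 21, 100_800)],
)
def test_count_released_matches_seasonal_totals(rate, days, expected):
    sched = ReleaseSchedule(
        "site", ReleaseDisk(6.3, 53.9), rate, dt.datetime(2022, 6, 15),
        dt.datetime(2022, 6, 15) + dt.timedelta(days=days),
    )
    assert count_released(sched) == expected


def test_disk_release_uniform_by_area():
    """E[r] = 2R/3 for a uniform disk; sqrt-uniform radial sampling."""
    sched = ReleaseSchedule(
        "site", ReleaseDisk(6.3, 53.9, radius_m=1000.0), 1,
        dt.datetime(2022, 6, 15), dt.datetime(2022, 6, 16), seed=2,
    )
    lon, lat = sample_release_positions(sched, n=10_000)
    d = _haversine_m(lon, lat, 6.3, 53.9)
    # placement is exact in the local tangent plane; haversine re-measurement
    # differs by the (sub-decimeter) projection distortion at 1 km scale
    assert d.max() <= 1000.0 + 0.05
    assert d.mean() == pytest.approx(2000.0 / 3.0, abs=10.0)


def test_polygon_release_inside_polygon():
    square = box(6.0, 54.0, 6.01, 54.01)
    sched = ReleaseSchedule(
        "poly", square, 1, dt.datetime(2022, 6, 15), dt.datetime(2022, 6, 16), seed=3
    )
    lon, lat = sample_release_positions(sched, n=500)
    assert np.all((lon >= 6.0) & (lon <= 6.01) & (lat >= 54.0) & (lat <= 54.01))


def test_release_positions_deterministic():
    sched = ReleaseSchedule(
        "site", ReleaseDisk(6.3, 53.9), 1, dt.datetime(2022, 6, 15),
        dt.datetime(2022, 6, 16), seed=11,
    )
    a = sample_release_positions(sched, n=100)
    b = sample_release_positions(sched, n=100)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


# ---------------------------------------------------------------------------
# interpolation


def test_velocity_at_cell_center_snapshot_is_exact():
    f = _uniform_field(days=1)
    f.u[2, 5, 7] = 0.33
    lon = f.grid.lon_centers[7]
    lat = f.grid.lat_centers[5]
    t = f.times[2]
    u, v = velocity_at(f, float(lon), float(lat), t)
    assert u == 0.33 and v == 0.0


def test_velocity_uniform_field_everywhere():
    f = _uniform_field(u=0.07, v=-0.02, days=1)
    for lon, lat in [(5.5, 53.2), (8.7, 55.1), (7.0, 54.0)]:
        u, v = velocity_at(f, lon, lat, T0 + dt.timedelta(hours=5, minutes=17))
        assert u == pytest.approx(0.07) and v == pytest.approx(-0.02)


def test_bilinear_midpoint_of_linear_field():
    f = _uniform_field(days=1)
    lon_c = f.grid.lon_centers
    f.u[:] = lon_c[None, None, :]  # linear in longitude
    mid = 0.5 * (lon_c[3] + lon_c[4])
    u, _ = velocity_at(f, float(mid), 54.0, f.times[0])
    assert u == pytest.approx(0.5 * (lon_c[3] + lon_c[4]))


def test_velocity_out_of_domain_raises():
    f = _uniform_field(days=1)
    with pytest.raises(OutOfDomainError):
        velocity_at(f, 4.0, 54.0, f.times[0])
    with pytest.raises(OutOfDomainError):
        velocity_at(f, 6.0, 54.0, T0 - dt.timedelta(hours=1))


# ---------------------------------------------------------------------------
# advection oracles


def test_zero_field_zero_displacement():
    f = _uniform_field(days=2)
    pos = advect((6.0, 54.0), T0, T0 + dt.timedelta(days=1), f, 465.0)
    assert pos == (6.0, 54.0)


def test_uniform_flow_one_day_oracle():
    """u = 0.1 m/s for 86,400 s -> 8,640 m along the 54N parallel, +/- 1 m."""
    f = _uniform_field(u=0.1, days=2)
    p0 = (6.0, 54.0)
    p1 = advect(p0, T0, T0 + dt.timedelta(days=1), f, 465.0)
    east_m = (p1[0] - p0[0]) / DEG_PER_M * np.cos(np.radians(54.0))
    assert east_m == pytest.approx(8640.0, abs=1.0)
    assert p1[1] == pytest.approx(54.0, abs=1e-12)


def test_solid_body_rotation_conserves_radius():
    """RK4 on a rotation field keeps |r| within 0.1% over one revolution."""
    lon0, lat0 = 7.0, 54.0
    g = GridSpec(6.0, 8.0, 53.5, 54.5, nx=50, ny=25, snapshot_interval=43200)
    f = _uniform_field(days=2, grid=g)
    omega = 2 * np.pi / 86_400.0  # one revolution per day
    x_m = (g.lon_centers[None, :] - lon0) / DEG_PER_M * np.cos(np.radians(lat0))
    y_m = (g.lat_centers[:, None] - lat0) / DEG_PER_M
    f.u[:] = -omega * y_m[None, :, :]
    f.v[:] = omega * x_m[None, :, :]

    start = (lon0 + 5000.0 * DEG_PER_M / np.cos(np.radians(lat0)), lat0)
    end = advect(start, T0, T0 + dt.timedelta(days=1), f, 465.0)
    r0 = _haversine_m(*start, lon0, lat0)
    r1 = _haversine_m(*end, lon0, lat0)
    assert abs(r1 - r0) / r0 < 1e-3


def test_forward_backward_reversibility():
    lon0, lat0 = 7.0, 54.0
    g = GridSpec(6.0, 8.0, 53.5, 54.5, nx=50, ny=25, snapshot_interval=43200)
    f = _uniform_field(days=2, grid=g)
    omega = 2 * np.pi / 86_400.0
    x_m = (g.lon_centers[None, :] - lon0) / DEG_PER_M * np.cos(np.radians(lat0))
    y_m = (g.lat_centers[:, None] - lat0) / DEG_PER_M
    f.u[:] = -omega * y_m[None, :, :]
    f.v[:] = omega * x_m[None, :, :]
    back = VelocityFieldSeries(g, f.times, -f.u, -f.v, f.water, f.layer_tag)

    start = (7.03, 54.02)
    mid = advect(start, T0, T0 + dt.timedelta(days=1), f, 465.0)
    out = advect(mid, T0, T0 + dt.timedelta(days=1), back, 465.0)
    assert _haversine_m(out[0], out[1], start[0], start[1]) < 10.0


def test_step_stalls_on_land():
    land = box(6.05, 53.0, 9.0, 55.5)
    recipe = FlowRecipe(
        tidal_amplitude_u=0, tidal_amplitude_v=0, residual_u=0.5, noise_sd=0,
        land_polygons=[land],
    )
    f = make_flow_field(GRID, recipe, T0, T0 + dt.timedelta(days=1))
    pos = (5.98, 54.0)
    # repeated steps push east into the land wall; the particle stalls at the coast
    for _ in range(300):
        pos = step(pos, T0, f, 465.0)
    assert 5.98 <= pos[0] < 6.0


# ---------------------------------------------------------------------------
# ensemble


def _schedule(rate=4, days=1, disk=ReleaseDisk(6.3, 54.0), seed=1):
    return ReleaseSchedule(
        "site", disk, rate, T0, T0 + dt.timedelta(days=days), seed=seed
    )


def test_zero_flow_settles_at_release_positions():
    f = _uniform_field(days=25)
    traj = run_ensemble(
        f, [_schedule()], _const_temps(), ScenarioConfig(pld_scenario="strict"),
        PLDParameters(mode="fixed_at_release"),
    )
    p = traj.particles
    assert (p["status"] == "settled").all()
    np.testing.assert_allclose(p["settlement_lon"], p["release_lon"], atol=1e-12)
    np.testing.assert_allclose(p["settlement_lat"], p["release_lat"], atol=1e-12)


def test_uniform_flow_settlement_displacement_oracle():
    """0.1 m/s east for PLD(15 degC) days -> ~129.6 km displacement."""
    f = _uniform_field(u=0.1, days=20)
    traj = run_ensemble(
        f, [_schedule(rate=2, disk=ReleaseDisk(5.6, 54.0, radius_m=200.0))],
        _const_temps(15.0), ScenarioConfig(pld_scenario="strict"),
        PLDParameters(mode="fixed_at_release"),
    )
    p = traj.particles
    assert (p["status"] == "settled").all()
    east_m = (
        (p["settlement_lon"] - p["release_lon"]).to_numpy()
        / DEG_PER_M
        * np.cos(np.radians(p["release_lat"].to_numpy()))
    )
    assert np.allclose(east_m, 129_619.0, atol=100.0)


def test_hard_stop_before_competency_means_no_settlement():
    f = _uniform_field(days=20)
    scenario = ScenarioConfig(pld_scenario="strict", hard_stop=T0 + dt.timedelta(days=3))
    traj = run_ensemble(f, [_schedule()], _const_temps(15.0), scenario,
                        PLDParameters(mode="fixed_at_release"))
    p = traj.particles
    assert (p["status"].isin(["drifting", "stalled"])).all()
    assert p["settlement_lon"].isna().all()


def test_particle_conservation_identity(tidal_run, residual_run):
    for traj in (tidal_run, residual_run):
        counts = traj.status_counts
        assert sum(counts.values()) == traj.n_released


def test_ensemble_deterministic():
    f = _uniform_field(u=0.05, v=0.02, days=20)
    args = ([_schedule(rate=2)], _const_temps(15.0), ScenarioConfig(pld_scenario="extended"))
    a = run_ensemble(f, *args)
    b = run_ensemble(f, *args)
    assert a.particles.equals(b.particles)
    assert a.samples.equals(b.samples)


def test_mismatched_layer_tags_rejected():
    f = _uniform_field(days=2, layer="depth_averaged")
    with pytest.raises(ConfigurationError):
        run_ensemble(f, [_schedule()], _const_temps(), ScenarioConfig(layer="surface"))
    with pytest.raises(ConfigurationError):
        run_ensemble(
            f, [_schedule()], _const_temps(layer="surface"),
            ScenarioConfig(layer="depth_averaged"),
        )


def test_pure_tidal_ensemble_center_of_gravity_returns():
    """Retention analog: after whole tidal periods the ensemble's center of
    gravity sits within one grid cell of the release center."""
    period = 44_712.0
    g = GridSpec(5.0, 9.0, 53.0, 55.5, nx=40, ny=25, snapshot_interval=int(period // 8))
    recipe = FlowRecipe(tidal_amplitude_u=0.4, tidal_amplitude_v=0.25, noise_sd=0)
    f = make_flow_field(g, recipe, T0, T0 + dt.timedelta(seconds=3 * period))
    sched = ReleaseSchedule("site", ReleaseDisk(6.5, 54.0, 1000.0), 1, T0,
                            T0 + dt.timedelta(hours=1), seed=8)
    lon, lat = sample_release_positions(sched, n=60)
    end_lon, end_lat = [], []
    t_end = T0 + dt.timedelta(seconds=2 * period)
    for x, y in zip(lon, lat):
        ex, ey = advect((x, y), T0, t_end, f, 465.0)
        end_lon.append(ex)
        end_lat.append(ey)
    assert abs(np.mean(end_lon) - lon.mean()) < g.dlon
    assert abs(np.mean(end_lat) - lat.mean()) < g.dlat
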