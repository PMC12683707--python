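"""Connectivity indices, retention, centers of gravity and distances."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from oysterdrift import (
    PointSite,
    RegionSet,
    ScenarioConfig,
    TrajectorySet,
    center_of_gravity,
    connectivity_index,
    connectivity_matrix,
    distance_km,
    in_region,
    self_recruitment,
)
from oysterdrift.errors import GeometryError, UndefinedIndexError


def _toy_traj(settle_lon, settle_lat, source="S", samples=None, statuses=None):
    n = len(settle_lon)
    t0 = np.datetime64("2022-06-15T00:00", "ms")
    particles = pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "source": source,
            "release_time": t0,
            "release_lon": settle_lon,
            "release_lat": settle_lat,
            "competency_start": t0 + np.timedelta64(15, "D"),
            "competency_end": t0 + np.timedelta64(29, "D"),
            "settlement_lon": settle_lon,
            "settlement_lat": settle_lat,
            "status": statuses if statuses is not None else "settled",
        }
    )
    if samples is None:
        samples = pd.DataFrame(
            columns=["particle_id", "source", "release_time", "time", "lon", "lat", "status"]
        )
    return TrajectorySet(particles, samples, ScenarioConfig())


# ---------------------------------------------------------------------------
# in_region


def test_polygon_membership_and_boundary():
    poly = box(6.0, 54.0, 6.4, 54.2)
    assert in_region(6.2, 54.1, poly)  # centroid
    assert in_region(6.0, 54.0, poly)  # vertex: boundary counts as inside
    assert not in_region(5.99, 54.1, poly)


def test_site_membership_threshold():
    site = PointSite(6.0, 54.0, radius_m=1000.0)
    on_radius = 6.0 + 999.0 / (111_194.9 * np.cos(np.radians(54.0)))
    beyond = 6.0 + 1001.0 / (111_194.9 * np.cos(np.radians(54.0)))
    assert in_region(on_radius, 54.0, site)
    assert not in_region(beyond, 54.0, site)


def test_invalid_polygon_rejected():
    bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
    with pytest.raises(GeometryError):
        in_region(0.5, 0.5, bowtie)


# ---------------------------------------------------------------------------
# connectivity_index on constructed trajectory sets


def test_all_settled_inside_sink_is_100():
    traj = _toy_traj(np.full(50, 6.2), np.full(50, 54.1))
    assert connectivity_index(traj, "S", box(6.0, 54.0, 6.4, 54.2), "strict") == 100.0


def test_disjoint_sink_is_0():
    traj = _toy_traj(np.full(50, 6.2), np.full(50, 54.1))
    assert connectivity_index(traj, "S", box(8.0, 54.0, 8.4, 54.2), "strict") == 0.0


def test_constructed_31_of_1000_gives_3_1_percent():
    lon = np.full(1000, 8.5)
    lon[:31] = 6.2  # exactly 31 settle in the sink
    traj = _toy_traj(lon, np.full(1000, 54.1))
    pct = connectivity_index(traj, "S", box(6.0, 54.0, 6.4, 54.2), "strict")
    assert pct == pytest.approx(3.1)


def test_zero_released_is_undefined_not_zero():
    traj = _toy_traj(np.array([6.2]), np.array([54.1]))
    with pytest.raises(UndefinedIndexError):
        connectivity_index(traj, "other-source", box(6.0, 54.0, 6.4, 54.2))


# ---------------------------------------------------------------------------
# matrix-level invariants on the synthetic study runs


def test_extended_dominates_strict_pairwise(tidal_run, residual_run, geometry):
    for traj in (tidal_run, residual_run):
        res = connectivity_matrix(traj, geometry)
        assert (res.extended.to_numpy() >= res.strict.to_numpy() - 1e-12).all()


def test_disjoint_partition_additivity(residual_run):
    """Strict arrivals over a disjoint partition of the domain sum exactly
    to the number of competency-reaching particles."""
    g = [5.4, 6.8, 7.5, 8.2]
    parts = {
        f"part{k}": box(g[k], 53.3, g[k + 1], 55.2) for k in range(3)
    }
    regions = RegionSet(polygons=parts, kinds={k: "mpa" for k in parts})
    res = connectivity_matrix(residual_run, regions)
    settled = int(np.isfinite(residual_run.particles["settlement_lon"]).sum())
    assert int(res.arrived_strict.sum(axis=1).iloc[0]) == settled
    expected_pct = 100.0 * settled / res.released.iloc[0]
    assert res.strict.sum(axis=1).iloc[0] == pytest.approx(expected_pct, abs=1e-9)


def test_center_of_gravity_mean_and_errors():
    traj = _toy_traj(np.array([6.0, 6.2, 6.0, 6.2]), np.array([54.0, 54.0, 54.2, 54.2]))
    lat, lon = center_of_gravity(traj)
    assert lat == pytest.approx(54.1) and lon == pytest.approx(6.1)
    with pytest.raises(UndefinedIndexError):
        center_of_gravity(_toy_traj(np.array([np.nan]), np.array([np.nan])))


def test_center_of_gravity_single_location():
    traj = _toy_traj(np.full(5, 6.3), np.full(5, 54.05))
    assert center_of_gravity(traj) == (54.05, 6.3)


@pytest.mark.parametrize(
    "a, b, expected, tol",
    [
        ((6.0, 54.0), (6.0, 54.0), 0.0, 0.0),
        ((6.0, 54.0), (6.0, 55.0), 111.19, 0.01),
        ((0.0, 0.0), (180.0, 0.0), np.pi * 6371.0, 1.0),
    ],
)
def test_distance_km_reference_values(a, b, expected, tol):
    assert distance_km(a, b) == pytest.approx(expected, abs=tol)


def test_self_recruitment_zero_flow_and_displacement():
    site = PointSite(6.2, 54.1, radius_m=1000.0)
    stay = _toy_traj(np.full(20, 6.2), np.full(20, 54.1), source="home")
    assert self_recruitment(stay, {"home": site})["home"] == 100.0
    # all particles carried > 1 km before competency
    gone_lon = 6.2 + 5000.0 / (111_194.9 * np.cos(np.radians(54.1)))
    gone = _toy_traj(np.full(20, gone_lon), np.full(20, 54.1), source="home")
    assert self_recruitment(gone, {"home": site})["home"] == 0.0


def test_self_recruitment_extended_dominates_strict(tidal_run, geometry):
    # release source is the MPA polygon; score against each site disk anyway
    for name, site in geometry.sites.items():
        strict = connectivity_index(tidal_run, "source-MPA", site, "strict")
        extended = connectivity_index(tidal_run, "source-MPA", site, "extended")
        assert extended >= strict


def test_formatted_matrix_one_decimal(tidal_run, geometry):
    res = connectivity_matrix(tidal_run, geometry)
    cell = res.formatted().iloc[0, 0]
    assert cell.count("(") == 1 and cell.endswith(")")
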