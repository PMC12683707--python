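"""Dispersal-footprint rasterization, overlap counts and the permutation null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oysterdrift import (
    DetectionSet,
    DispersalFootprint,
    GridSpec,
    ScenarioConfig,
    TrajectorySet,
    build_footprint,
    make_detections,
    overlap_count,
    overlap_null,
)
from oysterdrift.errors import ValidationError

GRID = GridSpec(5.0, 7.0, 53.0, 54.0, nx=40, ny=20)


def _traj_from_points(points, statuses=None, settle=None):
    """points: list of (lon, lat) samples for a single particle."""
    n = len(points)
    t0 = np.datetime64("2022-06-15T00:00", "ms")
    samples = pd.DataFrame(
        {
            "particle_id": 0,
            "source": "S",
            "release_time": t0,
            "time": t0 + np.arange(n).astype("timedelta64[h]"),
            "lon": [p[0] for p in points],
            "lat": [p[1] for p in points],
            "status": statuses if statuses is not None else "drift",
        }
    )
    particles = pd.DataFrame(
        {
            "particle_id": [0],
            "source": ["S"],
            "release_time": [t0],
            "release_lon": [points[0][0]],
            "release_lat": [points[0][1]],
            "competency_start": [t0 + np.timedelta64(15, "D")],
            "competency_end": [t0 + np.timedelta64(29, "D")],
            "settlement_lon": [settle[0] if settle else np.nan],
            "settlement_lat": [settle[1] if settle else np.nan],
            "status": ["drifting"],
        }
    )
    return TrajectorySet(particles, samples, ScenarioConfig())


def test_stationary_particle_occupies_one_cell():
    traj = _traj_from_points([(6.01, 53.51)] * 5)
    fp = build_footprint(traj, GRID)
    assert fp.strict_occupancy.sum() == 1
    assert fp.extended_occupancy.sum() == 1


def test_cell_walk_occupies_each_visited_cell():
    """Brute-force oracle: compare against directly indexing each sample."""
    rng = np.random.default_rng(4)
    pts = list(zip(5.0 + 2.0 * rng.random(60), 53.0 + rng.random(60)))
    traj = _traj_from_points(pts)
    fp = build_footprint(traj, GRID)
    expected = set()
    for lon, lat in pts:
        i = min(int((lon - 5.0) / 0.05), 39)
        j = min(int((lat - 53.0) / 0.05), 19)
        expected.add((j, i))
    assert set(zip(*np.nonzero(fp.strict_occupancy))) == expected


def test_out_of_bounds_samples_ignored_and_counted():
    traj = _traj_from_points([(6.0, 53.5), (10.0, 53.5), (6.0, 60.0)])
    fp = build_footprint(traj, GRID)
    assert fp.n_out_of_bounds == 2
    assert fp.strict_occupancy.sum() == 1


def test_empty_trajectory_gives_empty_footprint():
    empty = TrajectorySet(
        pd.DataFrame(columns=["particle_id", "source", "release_time", "release_lon",
                              "release_lat", "competency_start", "competency_end",
                              "settlement_lon", "settlement_lat", "status"]),
        pd.DataFrame(columns=["particle_id", "source", "release_time", "time",
                              "lon", "lat", "status"]),
        ScenarioConfig(),
    )
    fp = build_footprint(empty, GRID)
    assert fp.extended_occupancy.sum() == 0


def test_competent_samples_extend_but_do_not_shrink_strict():
    pts = [(6.0, 53.5), (6.2, 53.5), (6.4, 53.5)]
    statuses = ["drift", "drift", "competent"]
    traj = _traj_from_points(pts, statuses=statuses)
    fp = build_footprint(traj, GRID)
    assert fp.strict_occupancy.sum() == 2
    assert fp.extended_occupancy.sum() == 3
    assert not np.any(fp.strict_occupancy & ~fp.extended_occupancy)


def test_overlap_monotone_in_occupancy():
    det = make_detections(
        DispersalFootprint(GRID, np.ones((20, 40), bool), np.ones((20, 40), bool)),
        n_inside=10, n_outside=0, seed=1,
    )
    small = np.zeros((20, 40), bool)
    small[:10] = True
    big = np.ones((20, 40), bool)
    k_small, _, _ = overlap_count(det, DispersalFootprint(GRID, small, small))
    k_big, _, _ = overlap_count(det, DispersalFootprint(GRID, big, big))
    assert k_small <= k_big == 10


def test_station_outside_grid_flagged_never_counted():
    table = pd.DataFrame(
        {
            "station_id": ["in", "out"],
            "lon": [6.0, 12.0],
            "lat": [53.5, 53.5],
            "date": ["2022-06-28"] * 2,
            "method": ["eDNA", "meroplankton"],
            "detected": [True, True],
        }
    )
    det = DetectionSet(table)
    occ = np.ones((20, 40), bool)
    k, n, per = overlap_count(det, DispersalFootprint(GRID, occ, occ))
    assert (k, n) == (1, 2)
    assert bool(per.loc[per["station_id"] == "out", "out_of_domain"].iloc[0])


def test_method_vocabulary_enforced():
    table = pd.DataFrame(
        {
            "station_id": ["a"], "lon": [6.0], "lat": [53.5],
            "date": ["2022-06-28"], "method": ["sonar"], "detected": [True],
        }
    )
    with pytest.raises(ValidationError):
        DetectionSet(table)


# ---------------------------------------------------------------------------
# permutation null


def test_full_footprint_p_is_one():
    occ = np.ones((20, 40), bool)
    fp = DispersalFootprint(GRID, occ, occ)
    det = make_detections(fp, n_inside=8, n_outside=0, seed=2)
    p, null = overlap_null(det, fp, n_perm=99, seed=5)
    assert p == 1.0
    assert np.all(null == 8)


def test_empty_footprint_p_is_one():
    occ = np.zeros((20, 40), bool)
    fp = DispersalFootprint(GRID, occ, occ)
    det = DetectionSet(
        pd.DataFrame(
            {
                "station_id": ["a", "b"], "lon": [6.0, 6.5], "lat": [53.5, 53.6],
                "date": ["2022-06-28"] * 2, "method": ["eDNA", "eDNA"],
                "detected": [True, True],
            }
        )
    )
    p, _ = overlap_null(det, fp, n_perm=99, seed=5)
    assert p == 1.0


def test_permutation_p_matches_binomial_tail():
    """Half-occupied uniform footprint, 15 of 17 observed: the null is
    Bin(17, 0.5), whose tail P(K >= 15) ~ 0.00117."""
    rng = np.random.default_rng(10)
    occ = rng.random((20, 40)) < 0.5
    fp = DispersalFootprint(GRID, occ, occ)
    det = make_detections(fp, n_inside=15, n_outside=2, seed=3)
    k, n, _ = overlap_count(det, fp)
    assert (k, n) == (15, 17)
    p, null = overlap_null(det, fp, n_perm=4999, seed=7)
    f = occ.sum() / occ.size
    expected = float(stats.binom.sf(14, 17, f))
    assert p < 0.01
    assert p == pytest.approx(expected, abs=0.004)
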