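"""Readers and writers for the pipeline's on-disk formats.

Formats, all with lon before lat and UTC ISO-8601 timestamps:

* velocity series — CF-style gridded NetCDF (dims time/lat/lon; variables
  u, v in m/s and an integer water mask; time encoded as seconds since an
  epoch; grid bounds and layer tag as global attributes);
* regions — GeoJSON FeatureCollection (polygons with ``name``/``kind``
  properties, point sites with a ``radius_m`` property);
* temperature — CSV with columns date, temp_c, one row per day, no gaps;
* detections — CSV with columns station_id, lon, lat, date, method,
  detected;
* trajectories — two CSVs: a per-particle summary and the recorded
  position samples.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import mapping, shape

from .detections import DETECTION_COLUMNS, DetectionSet
from .errors import CoverageError, FormatError, ValidationError
from .fields import LAYERS, VelocityFieldSeries
from .grid import GridSpec
from .pld import TemperatureSeries
from .regions import PointSite, RegionSet
from .tracker import ScenarioConfig, TrajectorySet

_NC_ENGINE = "scipy"


# ---------------------------------------------------------------------------
# Velocity fields


def write_velocity(field: VelocityFieldSeries, path) -> None:
    g = field.grid
    ds = xr.Dataset(
        {
            "u": (("time", "lat", "lon"), field.u, {"units": "m s-1", "long_name": "eastward velocity"}),
            "v": (("time", "lat", "lon"), field.v, {"units": "m s-1", "long_name": "northward velocity"}),
            "mask": (
                ("lat", "lon"),
                field.water.astype(np.int8),
                {"flag_values": "0, 1", "flag_meanings": "land water"},
            ),
        },
        coords={
            "time": ("time", field.times),
            "lat": ("lat", g.lat_centers, {"units": "degrees_north"}),
            "lon": ("lon", g.lon_centers, {"units": "degrees_east"}),
        },
        attrs={
            "layer": field.layer_tag,
            "lon_min": g.lon_min,
            "lon_max": g.lon_max,
            "lat_min": g.lat_min,
            "lat_max": g.lat_max,
            "snapshot_interval": int(g.snapshot_interval),
            "Conventions": "CF-1.8",
        },
    )
    epoch = np.datetime_as_string(field.times[0].astype("datetime64[s]"))
    ds.to_netcdf(
        path,
        engine=_NC_ENGINE,
        encoding={"time": {"units": f"seconds since {epoch}", "dtype": "float64"}},
    )


def read_velocity(path) -> VelocityFieldSeries:
    """Read and validate a velocity series; zeroes any velocity on land.

    Missing variables or attributes raise :class:`FormatError` naming the
    element; non-monotone time raises :class:`ValidationError`; nonzero
    velocity on masked land cells triggers a warning and is zeroed.
    """
    with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
        ds = ds.load()
    for var in ("u", "v", "mask"):
        if var not in ds:
            raise FormatError(f"velocity file missing variable {var!r}")
    for attr in ("layer", "lon_min", "lon_max", "lat_min", "lat_max", "snapshot_interval"):
        if attr not in ds.attrs:
            raise FormatError(f"velocity file missing attribute {attr!r}")
    if ds.attrs["layer"] not in LAYERS:
        raise ValidationError(f"unknown layer tag {ds.attrs['layer']!r}")
    times = ds["time"].values
    if len(times) >= 2 and np.any(np.diff(times) <= np.timedelta64(0)):
        raise ValidationError("velocity time coordinate is not strictly increasing")
    grid = GridSpec(
        lon_min=float(ds.attrs["lon_min"]),
        lon_max=float(ds.attrs["lon_max"]),
        lat_min=float(ds.attrs["lat_min"]),
        lat_max=float(ds.attrs["lat_max"]),
        nx=ds.sizes["lon"],
        ny=ds.sizes["lat"],
        snapshot_interval=int(ds.attrs["snapshot_interval"]),
    )
    u = ds["u"].values.astype(float)
    v = ds["v"].values.astype(float)
    water = ds["mask"].values.astype(bool)
    if np.any(u[:, ~water] != 0) or np.any(v[:, ~water] != 0):
        warnings.warn("nonzero velocity on land cells; zeroing", stacklevel=2)
        u[:, ~water] = 0.0
        v[:, ~water] = 0.0
    return VelocityFieldSeries(
        grid=grid, times=times, u=u, v=v, water=water, layer_tag=str(ds.attrs["layer"])
    )


# ---------------------------------------------------------------------------
# Regions (GeoJSON)


def write_regions(regions: RegionSet, path) -> None:
    features = []
    for name, poly in regions.polygons.items():
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": {"name": name, "kind": regions.kinds.get(name, "mpa")},
            }
        )
    for name, site in regions.sites.items():
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [site.lon, site.lat]},
                "properties": {"name": name, "kind": "site", "radius_m": site.radius_m},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_regions(path) -> RegionSet:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"regions file is not valid JSON: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise FormatError("regions file is not a GeoJSON FeatureCollection")
    polygons, sites, kinds = {}, {}, {}
    seen = set()
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        name = props.get("name")
        if name is None:
            raise FormatError("region feature missing 'name' property")
        if name in seen:
            raise ValidationError(f"duplicate region name {name!r}")
        seen.add(name)
        geom = feat.get("geometry") or {}
        if geom.get("type") == "Point":
            lon, lat = geom["coordinates"][:2]
            sites[name] = PointSite(lon=lon, lat=lat, radius_m=float(props.get("radius_m", 1000.0)))
        else:
            polygons[name] = shape(geom)
            kinds[name] = props.get("kind", "mpa")
    return RegionSet(polygons=polygons, sites=sites, kinds=kinds)


# ---------------------------------------------------------------------------
# Temperature and detections (CSV)


def write_temperature(temps: TemperatureSeries, path) -> None:
    pd.DataFrame({"date": temps.dates.astype(str), "temp_c": temps.values}).to_csv(
        path, index=False
    )


def read_temperature(path, layer_tag: str = "surface") -> TemperatureSeries:
    df = pd.read_csv(path)
    for col in ("date", "temp_c"):
        if col not in df.columns:
            raise FormatError(f"temperature CSV missing column {col!r}")
    dates = pd.to_datetime(df["date"]).to_numpy().astype("datetime64[D]")
    if len(dates) == 0:
        raise FormatError("temperature CSV is empty")
    gaps = np.diff(dates) != np.timedelta64(1, "D")
    if np.any(gaps):
        first = dates[:-1][gaps][0] + np.timedelta64(1, "D")
        raise CoverageError(f"temperature series has a gap: missing day {first}")
    return TemperatureSeries(
        start_date=dates[0], values=df["temp_c"].to_numpy(dtype=float), layer_tag=layer_tag
    )


def write_detections(detections: DetectionSet, path) -> None:
    detections.table.to_csv(path, index=False)


def read_detections(path) -> DetectionSet:
    df = pd.read_csv(path)
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"detections CSV missing columns: {missing}")
    if df["detected"].dtype == object:
        df["detected"] = df["detected"].astype(str).str.lower().isin(("true", "1", "yes"))
    return DetectionSet(df)  # vocabulary check happens in DetectionSet


# ---------------------------------------------------------------------------
# Trajectories (CSV pair)


def write_trajectories(traj: TrajectorySet, particles_path, samples_path) -> None:
    traj.particles.to_csv(particles_path, index=False)
    traj.samples.to_csv(samples_path, index=False)


def read_trajectories(particles_path, samples_path, scenario: ScenarioConfig = None) -> TrajectorySet:
    particles = pd.read_csv(
        particles_path, parse_dates=["release_time", "competency_start", "competency_end"]
    )
    samples = pd.read_csv(samples_path, parse_dates=["release_time", "time"])
    if scenario is None:
        scenario = ScenarioConfig()
    return TrajectorySet(particles=particles, samples=samples, scenario=scenario)
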