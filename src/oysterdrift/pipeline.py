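"""Pipeline configuration and staged orchestration.

A :class:`PipelineConfig` is a plain nested mapping (YAML on disk) that
round-trips losslessly and hashes stably, describing: the synthetic
environment (grid, flow, temperature, geometry, detections fixture), the
drift scenario, the PLD parameters, the release schedules and the output
conventions.  The four stages — ``synth_env``, ``simulate``,
``connectivity`` and ``overlap`` — each read their declared inputs from
``workdir``, write their declared outputs there, and append to a run
manifest carrying the config hash, seeds, package versions and the
particle-conservation counts.

Default sizes are desk-scale: tens of particles per release hour over a
few seeding days rather than the study's 200-500/h over 21-61 days, so a
full run completes in minutes on one core.  The release arithmetic and all
indices are size-independent.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import io as od_io
from .connectivity import connectivity_matrix
from .detections import build_footprint, overlap_count, overlap_null
from .errors import ConfigurationError, UndefinedIndexError
from .grid import GridSpec
from .pld import PLDParameters
from .synthetic import (
    FlowRecipe,
    TemperatureRecipe,
    make_detections,
    make_flow_field,
    make_study_geometry,
    make_temperature_series,
)
from .tracker import ReleaseDisk, ReleaseSchedule, ScenarioConfig, TrajectorySet, run_ensemble

__version__ = "0.1.0"


def default_config(seed: int = 0) -> dict:
    """Desk-scale default study configuration on the synthetic geometry."""
    return {
        "seed": int(seed),
        "grid": {
            "lon_min": 5.4, "lon_max": 8.2, "lat_min": 53.3, "lat_max": 55.2,
            "nx": 56, "ny": 38, "snapshot_interval": 3600,
        },
        "window": {"start": "2022-06-15T00:00", "end": "2022-07-31T00:00"},
        "flow": {
            "tidal_amplitude_u": 0.35, "tidal_amplitude_v": 0.2,
            "tidal_period": 44712.0, "tidal_phase": 0.0,
            "residual_u": 0.0, "residual_v": 0.0, "noise_sd": 0.01,
        },
        "temperature": {
            "mean_annual": 11.0, "amplitude": 7.0, "peak_day_of_year": 220,
            "anomaly": 0.0, "noise_sd": 0.2,
        },
        "scenario": {
            "layer": "surface", "pld_scenario": "extended",
            "integration_step": 465.0, "output_interval": 3600.0, "hard_stop": None,
        },
        "pld": {
            "coefficient": 1025.315, "exponent": 1.56, "extension_days": 14.0,
            "mode": "development_integration",
        },
        "releases": [
            {"source": "source-MPA", "geometry": {"type": "region", "name": "source-MPA"},
             "rate_per_hour": 10, "start": "2022-06-15T00:00", "end": "2022-06-18T00:00"},
        ],
        "footprint": {"cell_size_deg": 0.05},
        "detections": {"n_inside": 15, "n_outside": 2},
        "overlap": {"n_perm": 999},
        "flags": {"drop_exited": False},
    }


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigurationError("config file must contain a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def _seeds(cfg: dict) -> dict:
    """Derive independent per-component seeds from the one config seed."""
    base = int(cfg.get("seed", 0))
    names = ("flow", "temperature", "releases", "detections", "overlap")
    return {name: (base * 1_000_003 + k * 7919) % (2**31 - 1) for k, name in enumerate(names)}


# ---------------------------------------------------------------------------
# Stage implementations


def _paths(workdir: Path) -> dict:
    workdir = Path(workdir)
    return {
        "velocity": workdir / "velocity.nc",
        "temperature": workdir / "temperature.csv",
        "regions": workdir / "regions.geojson",
        "detections": workdir / "detections.csv",
        "particles": workdir / "particles.csv",
        "samples": workdir / "samples.csv",
        "connectivity_wide": workdir / "connectivity_wide.csv",
        "connectivity_long": workdir / "connectivity_long.csv",
        "cog": workdir / "center_of_gravity.csv",
        "overlap": workdir / "overlap.json",
        "manifest": workdir / "manifest.json",
    }


def run_synth_env(cfg: dict, workdir) -> dict:
    """Generate velocity, temperature and region files from the recipes."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    p = _paths(workdir)
    seeds = _seeds(cfg)
    grid = GridSpec(**cfg["grid"])
    layer = cfg["scenario"]["layer"]
    flow = FlowRecipe(**cfg["flow"], seed=seeds["flow"])
    field = make_flow_field(
        grid, flow, cfg["window"]["start"], cfg["window"]["end"], layer_tag=layer
    )
    od_io.write_velocity(field, p["velocity"])
    temps = make_temperature_series(
        TemperatureRecipe(**cfg["temperature"], seed=seeds["temperature"]),
        cfg["window"]["start"],
        cfg["window"]["end"],
        layer_tag=layer,
    )
    od_io.write_temperature(temps, p["temperature"])
    regions = make_study_geometry(**cfg.get("geometry", {}))
    od_io.write_regions(regions, p["regions"])
    _update_manifest(cfg, workdir, stage="synth_env")
    return {"velocity": p["velocity"], "temperature": p["temperature"], "regions": p["regions"]}


def _build_schedules(cfg: dict, regions) -> list:
    seeds = _seeds(cfg)
    schedules = []
    for k, block in enumerate(cfg["releases"]):
        geom_spec = block["geometry"]
        if geom_spec["type"] == "disk":
            geom = ReleaseDisk(
                lon=geom_spec["lon"], lat=geom_spec["lat"],
                radius_m=geom_spec.get("radius_m", 1000.0),
            )
        elif geom_spec["type"] == "region":
            geom = regions.polygons[geom_spec["name"]]
        elif geom_spec["type"] == "site":
            site = regions.sites[geom_spec["name"]]
            geom = ReleaseDisk(lon=site.lon, lat=site.lat, radius_m=geom_spec.get("radius_m", 1000.0))
        else:
            raise ConfigurationError(f"unknown release geometry type {geom_spec['type']!r}")
        schedules.append(
            ReleaseSchedule(
                source_name=block["source"],
                geometry=geom,
                rate_per_hour=int(block["rate_per_hour"]),
                start=_dt.datetime.fromisoformat(block["start"]),
                end=_dt.datetime.fromisoformat(block["end"]),
                seed=int(block.get("seed", seeds["releases"] + k)),
            )
        )
    return schedules


def run_simulate(cfg: dict, workdir) -> TrajectorySet:
    """Advect the configured ensemble and write the trajectory tables."""
    workdir = Path(workdir)
    p = _paths(workdir)
    field = od_io.read_velocity(p["velocity"])
    scenario_cfg = dict(cfg["scenario"])
    hard_stop = scenario_cfg.pop("hard_stop", None)
    scenario = ScenarioConfig(
        **scenario_cfg,
        hard_stop=_dt.datetime.fromisoformat(hard_stop) if hard_stop else None,
    )
    temps = od_io.read_temperature(p["temperature"], layer_tag=scenario.layer)
    regions = od_io.read_regions(p["regions"])
    schedules = _build_schedules(cfg, regions)
    pld_params = PLDParameters(**cfg["pld"])
    traj = run_ensemble(field, schedules, temps, scenario, pld_params)
    od_io.write_trajectories(traj, p["particles"], p["samples"])
    _update_manifest(cfg, workdir, stage="simulate", counts=traj.status_counts,
                     released=traj.n_released)
    return traj


def run_connectivity(cfg: dict, workdir):
    """Score the connectivity matrix and write wide/long/center-of-gravity CSVs."""
    workdir = Path(workdir)
    p = _paths(workdir)
    traj = od_io.read_trajectories(p["particles"], p["samples"])
    if traj.n_released == 0:
        raise UndefinedIndexError("no particles in trajectory file; connectivity undefined")
    regions = od_io.read_regions(p["regions"])
    result = connectivity_matrix(
        traj, regions,
        scenario_tag=f"{cfg['scenario']['layer']}/{cfg['scenario']['pld_scenario']}",
        drop_exited=bool(cfg.get("flags", {}).get("drop_exited", False)),
    )
    result.formatted().to_csv(p["connectivity_wide"], index_label="source")
    result.long().to_csv(p["connectivity_long"], index=False)
    result.cog.to_csv(p["cog"], index=False)
    _update_manifest(cfg, workdir, stage="connectivity")
    return result


def run_overlap(cfg: dict, workdir) -> dict:
    """Footprint vs detections: counts, per-station flags, permutation p."""
    workdir = Path(workdir)
    p = _paths(workdir)
    seeds = _seeds(cfg)
    traj = od_io.read_trajectories(p["particles"], p["samples"])
    field = od_io.read_velocity(p["velocity"])
    cell = float(cfg.get("footprint", {}).get("cell_size_deg", 0.05))
    g = field.grid
    fgrid = GridSpec(
        lon_min=g.lon_min, lon_max=g.lon_max, lat_min=g.lat_min, lat_max=g.lat_max,
        nx=max(2, round((g.lon_max - g.lon_min) / cell)),
        ny=max(2, round((g.lat_max - g.lat_min) / cell)),
        snapshot_interval=g.snapshot_interval,
    )
    lon_c, lat_c = np.meshgrid(fgrid.lon_centers, fgrid.lat_centers)
    i, j = g.cell_index(lon_c.ravel(), lat_c.ravel())
    water = field.water[j, i].reshape(fgrid.ny, fgrid.nx)
    footprint = build_footprint(traj, fgrid, water=water,
                                scenario_tag=cfg["scenario"]["pld_scenario"])

    if p["detections"].exists():
        detections = od_io.read_detections(p["detections"])
    else:
        det_cfg = cfg.get("detections", {"n_inside": 15, "n_outside": 2})
        detections = make_detections(
            footprint, int(det_cfg["n_inside"]), int(det_cfg["n_outside"]),
            seed=seeds["detections"],
        )
        od_io.write_detections(detections, p["detections"])

    k, n, per_station = overlap_count(detections, footprint)
    n_perm = int(cfg.get("overlap", {}).get("n_perm", 999))
    pval, _ = overlap_null(detections, footprint, n_perm=n_perm, seed=seeds["overlap"])
    report = {
        "k": k,
        "n": n,
        "p_value": pval,
        "n_perm": n_perm,
        "occupied_cells": int(footprint.occupancy("union").sum()),
        "water_cells": int(footprint.water.sum()),
        "per_station": per_station.to_dict(orient="records"),
    }
    Path(p["overlap"]).write_text(json.dumps(report, indent=1, default=bool))
    _update_manifest(cfg, workdir, stage="overlap")
    return report


def run_all(cfg: dict, workdir) -> dict:
    run_synth_env(cfg, workdir)
    run_simulate(cfg, workdir)
    run_connectivity(cfg, workdir)
    return run_overlap(cfg, workdir)


def _update_manifest(cfg, workdir, stage, counts=None, released=None):
    import pandas
    import numpy

    p = _paths(workdir)["manifest"]
    manifest = json.loads(p.read_text()) if p.exists() else {
        "config_hash": config_hash(cfg),
        "seeds": _seeds(cfg),
        "versions": {
            "oysterdrift": __version__,
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
        },
        "stages": [],
    }
    entry = {"stage": stage}
    if counts is not None:
        entry["counts"] = counts
        entry["released"] = released
    manifest["stages"].append(entry)
    p.write_text(json.dumps(manifest, indent=1))
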