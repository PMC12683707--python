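"""Settlement accounting: source->sink connectivity, retention, dispersal centers.

A connectivity index is the percentage of particles released in a source
that arrive at a sink under the competency rules:

* **strict** — the settlement position (where the particle was the instant
  its pelagic stage completed) lies in the sink;
* **extended** — the particle's recorded positions enter the sink at least
  once during the competency window.

The denominator is *all released particles* of the source — including
stalled and domain-exited ones — unless ``drop_exited`` removes the
latter.  Overlapping sinks are scored independently (a larva settling in a
restoration site also counts toward the MPA that contains it); rows are
not normalized.

Self-recruitment is the same index with the sink equal to the natal site's
1-km disk.  The center of gravity of a run is the unweighted mean
latitude/longitude of settlement positions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .errors import GeometryError, UndefinedIndexError
from .regions import PointSite, RegionSet
from .tracker import TrajectorySet

R_EARTH_KM = 6371.0


def distance_km(a, b) -> float:
    """Haversine great-circle distance between (lon, lat) points, in km."""
    lon1, lat1 = np.radians(np.asarray(a, dtype=float))
    lon2, lat2 = np.radians(np.asarray(b, dtype=float))
    s = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * R_EARTH_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0))))


def _haversine_m(lon, lat, lon0, lat0):
    lon, lat = np.radians(np.asarray(lon, float)), np.radians(np.asarray(lat, float))
    lon0, lat0 = np.radians(lon0), np.radians(lat0)
    s = np.sin((lat - lat0) / 2) ** 2 + np.cos(lat) * np.cos(lat0) * np.sin((lon - lon0) / 2) ** 2
    return 2 * R_EARTH_KM * 1000.0 * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))


def region_contains(region, lon, lat) -> np.ndarray:
    """Vectorized membership; polygon boundaries count as inside."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if isinstance(region, PointSite):
        return _haversine_m(lon, lat, region.lon, region.lat) <= region.radius_m
    if isinstance(region, BaseGeometry):
        if not region.is_valid:
            raise GeometryError("invalid region polygon")
        return shapely.intersects(region, shapely.points(lon, lat))
    raise GeometryError(f"unsupported region type {type(region).__name__}")


def in_region(lon: float, lat: float, region) -> bool:
    """Point membership for a single coordinate pair."""
    return bool(region_contains(region, lon, lat)[0])


def _resolve(regions, sink):
    if isinstance(sink, str):
        return regions[sink]
    return sink


def _arrival_counts(traj: TrajectorySet, source: str, sink, drop_exited: bool):
    """(released, strict_arrived, extended_arrived) integer counts."""
    part = traj.particles[traj.particles["source"] == source]
    released = len(part)
    if drop_exited:
        released -= int((part["status"] == "exited").sum())
    if released == 0:
        raise UndefinedIndexError(f"no released particles for source {source!r}")

    settled = part[np.isfinite(part["settlement_lon"].to_numpy(dtype=float))]
    if len(settled):
        strict_hits = region_contains(
            sink, settled["settlement_lon"].to_numpy(), settled["settlement_lat"].to_numpy()
        )
        strict_arrived = int(strict_hits.sum())
    else:
        strict_arrived = 0

    comp = traj.samples[
        (traj.samples["source"] == source) & (traj.samples["status"] == "competent")
    ]
    arrived_ids = set()
    if len(comp):
        hits = region_contains(sink, comp["lon"].to_numpy(), comp["lat"].to_numpy())
        arrived_ids.update(comp.loc[hits, "particle_id"].tolist())
    if len(settled):
        arrived_ids.update(settled.loc[strict_hits, "particle_id"].tolist())
    return released, strict_arrived, len(arrived_ids)


def connectivity_index(
    traj: TrajectorySet, source: str, sink, scenario: str = "strict", *,
    regions: RegionSet | None = None, drop_exited: bool = False,
) -> float:
    """Percentage of released source particles arriving at ``sink``."""
    sink = _resolve(regions, sink) if regions is not None else sink
    released, strict_n, ext_n = _arrival_counts(traj, source, sink, drop_exited)
    n = strict_n if scenario == "strict" else ext_n
    return 100.0 * n / released


def center_of_gravity(traj: TrajectorySet, source: str | None = None):
    """Unweighted mean (lat, lon) of settlement positions.

    Raises :class:`UndefinedIndexError` when no particle reached
    settlement competency.
    """
    part = traj.particles
    if source is not None:
        part = part[part["source"] == source]
    ok = np.isfinite(part["settlement_lon"].to_numpy(dtype=float))
    if not ok.any():
        raise UndefinedIndexError("no settled particles: center of gravity undefined")
    return (
        float(part["settlement_lat"].to_numpy()[ok].mean()),
        float(part["settlement_lon"].to_numpy()[ok].mean()),
    )


def self_recruitment(
    traj: TrajectorySet, sites: dict, scenario: str = "strict", drop_exited: bool = False
) -> dict:
    """Per-site percentage of larvae arriving back within the natal radius.

    ``sites`` maps source names (matching release source names) to
    :class:`PointSite` objects; the default 1-km radius is the study's
    self-recruitment threshold.
    """
    out = {}
    for name, site in sites.items():
        out[name] = connectivity_index(traj, name, site, scenario, drop_exited=drop_exited)
    return out


class ConnectivityResult:
    """Strict/extended connectivity matrices plus dispersal summaries.

    Attributes
    ----------
    strict, extended : pd.DataFrame
        Percentages, rows = sources, columns = sinks.
    released : pd.Series
        Denominator per source.
    arrived_strict, arrived_extended : pd.DataFrame
        Raw integer counts.
    cog : pd.DataFrame
        Per-source mean settlement (lat, lon) and distance (km) from the
        settlement center of gravity to each polygon region's centroid.
    scenario_tag : str
    """

    def __init__(self, scenario_tag, strict, extended, released, arrived_strict,
                 arrived_extended, cog):
        self.scenario_tag = scenario_tag
        self.strict = strict
        self.extended = extended
        self.released = released
        self.arrived_strict = arrived_strict
        self.arrived_extended = arrived_extended
        self.cog = cog

    def formatted(self) -> pd.DataFrame:
        """Table-style "strict (extended)" cells, one decimal place."""
        out = self.strict.copy().astype(object)
        for r in out.index:
            for c in out.columns:
                out.loc[r, c] = f"{self.strict.loc[r, c]:.1f} ({self.extended.loc[r, c]:.1f})"
        return out

    def long(self) -> pd.DataFrame:
        """Tidy long-format variant: source, sink, strict_pct, extended_pct."""
        rows = []
        for src in self.strict.index:
            for snk in self.strict.columns:
                rows.append(
                    {
                        "source": src,
                        "sink": snk,
                        "strict_pct": self.strict.loc[src, snk],
                        "extended_pct": self.extended.loc[src, snk],
                        "released": int(self.released[src]),
                        "arrived_strict": int(self.arrived_strict.loc[src, snk]),
                        "arrived_extended": int(self.arrived_extended.loc[src, snk]),
                    }
                )
        return pd.DataFrame(rows)


def connectivity_matrix(
    traj: TrajectorySet, regions: RegionSet, scenario_tag: str = "", drop_exited: bool = False
) -> ConnectivityResult:
    """Score every (release source) x (named region) pair.

    Overlapping and nested sinks are evaluated independently.  The
    extended entry dominates the strict entry pairwise because the
    settlement position is itself one of the competency-window samples.
    """
    sources = list(dict.fromkeys(traj.particles["source"]))
    sinks = regions.names
    strict = pd.DataFrame(0.0, index=sources, columns=sinks)
    extended = pd.DataFrame(0.0, index=sources, columns=sinks)
    a_strict = pd.DataFrame(0, index=sources, columns=sinks)
    a_ext = pd.DataFrame(0, index=sources, columns=sinks)
    released = pd.Series(0, index=sources, dtype=int)

    for src in sources:
        for snk in sinks:
            rel, s_n, e_n = _arrival_counts(traj, src, regions[snk], drop_exited)
            released[src] = rel
            a_strict.loc[src, snk] = s_n
            a_ext.loc[src, snk] = e_n
            strict.loc[src, snk] = 100.0 * s_n / rel
            extended.loc[src, snk] = 100.0 * e_n / rel

    cog_rows = []
    for src in sources:
        try:
            lat, lon = center_of_gravity(traj, src)
        except UndefinedIndexError:
            lat = lon = np.nan
        row = {"source": src, "cog_lat": lat, "cog_lon": lon}
        for name, poly in regions.polygons.items():
            c = poly.centroid
            row[f"dist_km_to_{name}"] = (
                distance_km((lon, lat), (c.x, c.y)) if np.isfinite(lat) else np.nan
            )
        cog_rows.append(row)

    return ConnectivityResult(
        scenario_tag, strict, extended, released, a_strict, a_ext, pd.DataFrame(cog_rows)
    )
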