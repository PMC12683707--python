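"""Shared fixtures: synthetic study geometry and mid-size ensemble runs.

The two session-scoped ensembles mirror the study's contrast between a
calm, tide-dominated year (high local retention) and a year with a steady
wind-driven residual pointing from the source MPA toward the sink MPA
(enhanced long-distance transport).  They are reused by the connectivity,
footprint and acceptance tests to keep the suite fast.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("repro", derandomize=True, deadline=None)
_hyp_settings.load_profile("repro")

from oysterdrift import (
    FlowRecipe,
    GridSpec,
    ReleaseSchedule,
    ScenarioConfig,
    TemperatureRecipe,
    make_flow_field,
    make_study_geometry,
    make_temperature_series,
    run_ensemble,
)
from oysterdrift.pld import PLDParameters

T_START = dt.datetime(2022, 6, 15)
T_END = dt.datetime(2022, 7, 31)

STUDY_GRID = GridSpec(
    lon_min=5.4, lon_max=8.2, lat_min=53.3, lat_max=55.2, nx=56, ny=38, snapshot_interval=3600
)

# steady residual aimed from the source-MPA center toward the sink-MPA center
RESIDUAL_U, RESIDUAL_V = 0.071, 0.097


@pytest.fixture(scope="session")
def geometry():
    return make_study_geometry()


@pytest.fixture(scope="session")
def temps():
    return make_temperature_series(
        TemperatureRecipe(noise_sd=0.2, seed=11), T_START, T_END, layer_tag="surface"
    )


def _run(layer, residual_u, residual_v, n_particles=10_008, seed=5):
    recipe = FlowRecipe(
        tidal_amplitude_u=0.35,
        tidal_amplitude_v=0.2,
        residual_u=residual_u,
        residual_v=residual_v,
        noise_sd=0.01,
        seed=seed,
    )
    field = make_flow_field(STUDY_GRID, recipe, T_START, T_END, layer_tag=layer)
    temps = make_temperature_series(
        TemperatureRecipe(noise_sd=0.2, seed=11), T_START, T_END, layer_tag=layer
    )
    regions = make_study_geometry()
    rate = max(1, n_particles // 72)  # 3 seeding days, hourly releases
    schedule = ReleaseSchedule(
        source_name="source-MPA",
        geometry=regions.polygons["source-MPA"],
        rate_per_hour=rate,
        start=T_START,
        end=T_START + dt.timedelta(days=3),
        seed=seed + 1,
    )
    scenario = ScenarioConfig(layer=layer, pld_scenario="extended")
    return run_ensemble(field, [schedule], temps, scenario, PLDParameters())


@pytest.fixture(scope="session")
def tidal_run():
    """Tide-only, depth-averaged analog: oscillatory currents, no residual."""
    return _run("depth_averaged", 0.0, 0.0)


@pytest.fixture(scope="session")
def residual_run():
    """Surface analog of a windy year: residual aimed source -> sink."""
    return _run("surface", RESIDUAL_U, RESIDUAL_V)
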