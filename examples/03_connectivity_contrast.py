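"""Source-sink connectivity: tide-only retention vs wind-driven transport.

Reproduces the package's central mechanism on the synthetic geometry: with
tidal currents alone larvae stay near the source MPA (high retention, no
sink arrivals); adding a steady residual aimed at the sink MPA reverses
the pattern, the analog of a year with persistent south-westerly winds.
"""

import datetime as dt

from oysterdrift import (
    FlowRecipe,
    GridSpec,
    PLDParameters,
    ReleaseSchedule,
    ScenarioConfig,
    TemperatureRecipe,
    connectivity_matrix,
    make_flow_field,
    make_study_geometry,
    make_temperature_series,
    run_ensemble,
)

t0, t1 = dt.datetime(2022, 6, 15), dt.datetime(2022, 7, 31)
grid = GridSpec(5.4, 8.2, 53.3, 55.2, nx=56, ny=38, snapshot_interval=3600)
regions = make_study_geometry()

for label, (ru, rv), layer in [
    ("tide only (calm year, depth-averaged)", (0.0, 0.0), "depth_averaged"),
    ("tide + residual toward sink (windy year, surface)", (0.071, 0.097), "surface"),
]:
    recipe = FlowRecipe(tidal_amplitude_u=0.35, tidal_amplitude_v=0.2,
                        residual_u=ru, residual_v=rv, noise_sd=0.01, seed=1)
    field = make_flow_field(grid, recipe, t0, t1, layer_tag=layer)
    temps = make_temperature_series(TemperatureRecipe(noise_sd=0.2, seed=2), t0, t1,
                                    layer_tag=layer)
    schedule = ReleaseSchedule("source-MPA", regions.polygons["source-MPA"], 10,
                               t0, t0 + dt.timedelta(days=3), seed=3)
    traj = run_ensemble(field, [schedule], temps,
                        ScenarioConfig(layer=layer, pld_scenario="extended"),
                        PLDParameters())
    res = connectivity_matrix(traj, regions)
    print(f"\n{label}  ({traj.n_released} particles)")
    print("  connectivity, % of released, strict (extended):")
    print("   source retention:", res.formatted().loc["source-MPA", "source-MPA"])
    print("   source -> sink:  ", res.formatted().loc["source-MPA", "sink-MPA"])
# Retention collapses and sink connectivity jumps once the residual is on:
# wind-driven currents, not the tide, decide between local recruitment and
# long-distance dispersal.
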