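# Methods

This note documents the models, numerical choices and limitations behind
`oysterdrift`, in the spirit of a model-description appendix.

## Larval development and settlement competency

The pelagic larval duration follows a power law of daily mean water
temperature, `PLD_days = c·T^(−b)` with defaults `c = 1025.315`,
`b = 1.56` (dimensionless; `T` in °C). The law is undefined for `T ≤ 0`
and the code raises a domain error there rather than extrapolating.

Because temperature changes while a larva drifts, the completion of the
pelagic stage is computed in one of two modes:

* `development_integration` (default): a daily development fraction
  `1/PLD(T_d)` is accumulated from release; the stage completes when the
  sum reaches 1. The crossing is interpolated linearly within the
  crossing day, so competency times are continuous rather than quantized
  to whole days — this matters downstream, where settlement positions are
  taken at the exact competency instant. We default to integration
  because the law is defined in terms of the *daily* mean temperature
  over a season in which water warms by several degrees during a single
  drift; evaluation once at release (`fixed_at_release`) is provided for
  comparison, and the two agree exactly for constant temperature.
* The temperature input is a single regional daily series per drift
  layer, not temperature sampled along each trajectory. This mirrors the
  intended use (basin-averaged reanalysis series) and makes competency a
  function of release time only, which the ensemble runner exploits by
  computing one settlement window per hourly release cohort.

The **strict** scenario settles the larva at the instant of completion;
the **extended** scenario keeps it drifting and competent for a further
`extension_days` (default 14), during which arrival at a sink counts on
first contact. Extended-minus-strict equals the extension exactly by
construction.

Spawning onset is the first day whose mean temperature exceeds 15 °C
*and* on which cumulative degree-days since the series start reach 570.
The degree-day baseline defaults to 0 °C and is configurable, since
published degree-day criteria for oyster conditioning vary in their
baseline; a fixed calendar onset (June 15 in the bundled configurations)
overrides both rules. When the thresholds are never met the function
returns "no onset" (`None`) rather than raising, because an absent
spawning season is a valid model outcome.

## Advection

Particles are advected in WGS84 lon/lat with the local-metric conversion
`dlon = u·dt/(R cos φ · π/180)`, `dlat = v·dt/(R·π/180)`,
`R = 6,371,000 m`, using fixed-step classical RK4 at 465 s (an explicit
Euler scheme is available for sensitivity checks). Velocity is
interpolated bilinearly between the four surrounding cell centers and
linearly in time between snapshots; interpolation weights within 1e-9 of
a node are snapped so that queries at cell centers return stored values
exactly. Land cells carry zero velocity and keep their interpolation
weight, which smoothly decelerates particles approaching a coast.

Sub-steps are truncated so each particle lands exactly on (i) its hourly
output marks, (ii) its competency-start instant and (iii) its stop time.
This makes recorded samples carry exact nominal timestamps and lets the
uniform-flow oracle (0.1 m/s for one day → 8,640 m) hold to better than
1 m even though 86,400 s is not a multiple of 465 s.

Boundary rules: a step ending on a land cell is discarded and the
particle stalls in place (tidal reversal can free it); a step leaving the
domain freezes the particle at its last in-domain position with status
`exited`. Stalling was chosen over reflection or removal because it is
conservative and keeps the bookkeeping identity exact: at all times every
released particle is in exactly one of {drifting, competent, settled,
stalled, exited}, where `competent` is the drifting sub-state inside the
extended competency window. Exited particles stay in connectivity
denominators by default (`drop_exited` removes them), matching a literal
"percent of released larvae" convention.

Releases are placed on the hour, start-inclusive and end-exclusive — the
only convention consistent with the seasonal totals (200/h × 24 × 61 d =
292,800). Disk releases are uniform by area (sqrt-uniform radius);
polygon releases use rejection sampling in the bounding box; draws on
land are redrawn. No diffusion/random-walk term is added: drift is
purely advective, with any stochasticity entering through the velocity
field itself.

## Connectivity accounting

Polygon membership is boundary-inclusive; point sites use a great-circle
radius (1 km by default, the same threshold that defines
self-recruitment). Overlapping or nested sinks are scored independently
and rows are not normalized, so a larva settling in a restoration site
also counts toward the MPA containing it. Extended-scenario arrival is
evaluated on the stored hourly samples, not per 465-s integration step; a
larva that crosses a sink entirely within one output interval can
therefore be missed. This is a deliberate resolution-dependent
approximation that bounds memory, and the output interval is
configurable. The settlement position is itself recorded as a
competency-window sample, which guarantees extended ≥ strict pairwise.
Percentages are reported to one decimal in formatted output; internal
values are exact ratios of integer counts.

## Dispersal footprint and detection concordance

The footprint rasterizes recorded samples onto a regular grid (0.05°
cells by default — fine enough that station-in-footprint counts are
stable against jitter, coarse enough to keep the occupancy array tiny)
with half-open cell membership, so a station on a cell edge belongs to
exactly one cell. Strict-phase occupancy uses pre-competency samples
plus settlement positions; extended-phase occupancy is cumulative and
hence a superset. Detection dates are not matched to trajectory times by
default: the comparison is against the whole simulated drift area, with
the per-phase restriction available. Since raw "k of n" counts carry no
significance on their own, a permutation null re-places stations
independently and uniformly over water cells; for spatially uniform
occupancy of fraction f the null is Binomial(n, f), which the tests use
as a closed-form cross-check.

## Synthetic environment

The generator emulates the statistical structure the analysis assumes,
not the hydrodynamics themselves:

* **Currents** — a sinusoidal tide (default period 44,712 s, the M2
  constituent, chosen because the study region is semidiurnal-tide
  dominated; the v-component is phase-shifted 90° by default so the tide
  traces an ellipse), plus a steady wind-driven residual, plus white
  noise (default 0.01–0.02 m/s) that is uncorrelated in space and time.
  Tidal amplitudes of 0.2–0.5 m/s and residuals around 0.1 m/s are
  typical of the southern North Sea.
* **Temperature** — annual mean 11 °C, seasonal amplitude 7 °C peaking at
  day 220 (early August): a German Bight-like cycle that crosses the
  15 °C spawning threshold in mid-June, so the thermal onset rules and
  the June-15 campaign override land within a day of each other.
* **Geometry** — rectangles with the real topology: a southern source MPA
  holding the three restoration sites at their published coordinates
  (BRG-DE 53.9166° N 6.2802° E, BRG-NL 53.7017° N 6.3490° E, Gemini-NL
  54.0107° N 6.0777° E), a transit gap, and a sink MPA ~110 km to the
  northeast. Real MPA shapefiles can be supplied through the GeoJSON
  reader instead.
* **Detections** — stations sampled from occupied/unoccupied water cells
  of a given footprint, so overlap counts are known by construction
  (e.g. 15 inside, 2 outside).

What the synthetic environment does *not* have: spatially sheared or
baroclinic currents, storm events, spatially correlated noise, realistic
coastlines, or any feedback of larvae on flow. Tests passing on it
demonstrate that the pipeline's accounting, numerics and invariants are
correct under known conditions — not that its predictions transfer to a
specific real velocity product, which must be supplied as input for real
applications.

## Problem sizes and determinism

The bundled configurations and tests run tens of thousands of particles
over a 2.8° × 1.9° domain with hourly snapshots over ~6 weeks; the
package's own validation uses ~10⁴-particle ensembles (releases over
three seeding days) and ~3 × 10³-particle ensembles in the acceptance
script, sizes at which all reported invariants are already exact and the
mechanism contrasts are unambiguous. Full study-scale schedules
(292,800–732,000 particles over 61 days) use the identical code path —
`count_released` and the release arithmetic are checked at that scale —
and simply cost proportionally more time and memory.

Every stochastic component (flow noise, temperature noise, release
sampling, detection placement, permutation null) draws from its own
`numpy` generator seeded from a single configuration seed, so reruns are
bit-identical; the acceptance script and the run manifest both verify
this by hashing output tables.

## Known limitations

* 2-D horizontal transport only; vertical larval behavior enters solely
  through the choice of surface vs depth-averaged layer.
* No larval mortality, growth or feeding; connectivity percentages are
  transport probabilities, not recruitment rates.
* Extended-arrival detection is limited by the output sampling interval
  (above), and footprint membership by the raster cell size.
* The stall-at-coast rule concentrates particles at land boundaries
  rather than resuspending them; with strong onshore residuals this
  inflates near-shore occupancy.
* Temperature is regional, so two larvae released the same hour share a
  competency window regardless of where they drift.
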