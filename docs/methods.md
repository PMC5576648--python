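# Methods

`thermofront` analyses satellite telemetry tracks of marine animals relative
to thermo-biological ocean fronts: the bands of strong SST gradient that form
along the edges of upwelling systems (the equatorial Pacific cold tongue, an
eastern-boundary coastal plume) and that concentrate planktonic food. The
package implements the full chain from raw Argos fixes to frontal-occupancy
statistics, and ships a synthetic ocean/track generator so every stage can be
tested end to end against known ground truth.

## Track quality control

Raw Argos fixes (tag id, UTC timestamp, lat/lon, location class 3/2/1/0/A/B)
are screened with an iterative forward/backward averaging speed filter. For
every retained fix the filter computes the root-mean-square of travel speeds
to up to `window` retained neighbours on each side (default 2), using WGS-84
Vincenty distances. The fix with the largest RMS above `vmax` (default
5 m s⁻¹) is removed and the speeds recomputed, until no fix exceeds the
limit. Endpoints only have one-sided speeds and are removed only when every
available speed exceeds the limit; ties are broken toward the earlier
timestamp, making the filter deterministic and idempotent. The default
`vmax` of 5 m s⁻¹ is conservative for an animal whose sustained speeds are
~1–1.5 m s⁻¹ while still catching the gross Argos failures (tens to hundreds
of km) the filter exists for.

One position per tag per UTC day is then selected: restrict to the best
available location class (3 ≻ 2 ≻ 1 ≻ 0 ≻ A ≻ B), then take the fix closest
to 12:00 UTC (ties to the earlier fix). UTC day boundaries are used
throughout because tracks can span several time zones. Tag detachment is a
per-tag configured end date, not inferred.

Classes 1 and 0 are ranked between {3,2} and {A,B} by Argos convention; the
per-class error magnitudes are configurable scenario parameters, not claims
about any particular tag hardware.

## SST handling and animal-centric sections

Daily gridded SST (CF-style netCDF, cell-centre registration) is averaged to
3-day composites to reduce noise: a per-cell mean over the available,
unmasked slices of the centred 3-day window, masked only where all slices
are masked. Long-term means are per-cell means over a time period.

For each daily position, a 1-D SST section is extracted from the composite
nearest in time (ties to the earlier composite), along the grid column
through the animal for the equatorial analysis (meridional section) or the
grid row for the coastal analysis (zonal section). The grid line is linearly
interpolated to the animal's exact off-grid longitude (resp. latitude), and
one extra sample is bilinearly interpolated at the animal itself. The
coordinate axis is then re-referenced to geodesic distance from the animal —
0 at the animal, positive north (meridional) or east (zonal) — because the
front's latitude varies by hundreds of km and a fixed geographic frame would
smear its structure across sections. The default half-length of 800 km
leaves room for both front edges beyond the displayed ±500 km.

Geodesics are computed with a vectorized Vincenty inverse on WGS-84 (the
conventional choice for Argos track analysis), with a closed-form meridian
arc series for meridional distances and a great-circle fallback for the
never-realistic near-antipodal pairs. Agreement with an independent
implementation (R `geosphere`) is at the 10⁻¹¹ relative level.

## Two-edge front detection

A front on a section is bounded by the **temperature minimum** on the
equatorward/inshore side (the coldest upwelled water) and the **slope
break** on the poleward/offshore side, where the strong frontal gradient
drops abruptly to the weak background gradient. Detection runs in one code
path for both orientations by flipping the axis so "poleward/offshore" is
positive, and has two stages:

1. **Coarse localisation.** The section is smoothed with a running mean of
   half-width `smooth_km` (50 km). The minimum of the smoothed profile is
   taken within the search window [−800, +200] km around the animal. A
   windowed central-difference gradient (window 100 km) is then scanned
   poleward from the minimum; the slope break is the first location at least
   `min_front_km` (100 km) beyond the minimum where the gradient falls below
   `break_frac` (0.25) of the maximum gradient seen so far and stays below
   it for `sustain_km` (100 km).
2. **Local refinement.** Around each coarse edge, a continuous two-segment
   linear ("hinge") model is least-squares fitted to the raw section at each
   candidate breakpoint within ±150 km, followed by a bounded continuous
   optimisation between the best candidate's neighbours.

The refinement exists because any purely gradient-threshold rule carries
systematic offsets on piecewise-linear profiles — roughly
`grad_window × (0.5 − break_frac)` ≈ 25 km on the break, and a
smoothing-induced shift on an asymmetric V-minimum — which would bias the
occupancy statistic by several percent. With refinement, median edge errors
on noisy synthetic profiles (noise 0.1 °C) are 3–5 km and the percent-
distance estimator is unbiased to ~0.1 %. Sections with no gradient
structure (maximum windowed gradient below 0.3 °C/100 km) are flagged
`no_front` and excluded from aggregates but counted; edges pinned at window
boundaries are flagged likewise. All five detector parameters are exposed in
config and echoed into run metadata.

## Occupancy statistics

Each position is summarised as **percent distance**
`100 · (0 − d_min) / (d_break − d_min)`: 0 % at the temperature minimum,
100 % at the slope break, negative beyond the cold side and above 100 %
beyond the warm side (both retained, not discarded). Aggregations report
fractions in the half-open bands [0, 100) ("in front"), [50, 100) (warm
half) and [0, 120) (front plus its immediate periphery), plus a binned
histogram (10 % bins). Whether a position at exactly 100 % counts as inside
is not decidable from first principles; half-open intervals are used and
documented.

The 2-D distance × SST histogram counts section samples in 50 km × 0.5 °C
bins (edges aligned at 0 km and integer °C) and normalises each distance
column by its own total, so each column is a conditional SST distribution at
that distance from the animal; the mean SST interpolated at distance 0
summarises the water the animals actually occupy.

## Movement versus currents

Zonal movement speed is computed for consecutive daily-position pairs
separated by at most 3 days (larger gaps are skipped and counted): the
signed east–west geodesic distance along the parallel at the pair's mean
latitude, divided by the elapsed time between the two selected fixes,
positive eastward and wrap-safe across the antimeridian. Each pair is
matched with the zonal surface current at the grid node nearest the pair
midpoint in space and at the time slice nearest the pair mid-time (ties to
the lower index); the midpoint convention is recorded in output metadata.
Agreement is summarised by paired 0.2 m s⁻¹ speed histograms and by r² —
the squared Pearson correlation, i.e. the fraction of variance in animal
speeds explained by the currents (not a regression-through-origin R²). Zero
variance in either series yields a null r² with a reason.

## Time-at-temperature

Archival tags report, per 12-hour window, the fraction of time in
temperature bins with boundaries 0, 5, 10, 15, 18, 20, 22, 24, 26, 28,
30, >30 °C (11 bins, lower-closed). Windows are anchored at 00:00/12:00 UTC
(dawn/dusk at UTC−6); no day/night split is attempted because the animals
cross time zones. Since windows have equal length, time-weighted aggregation
is a simple mean, per tag or pooled; `fraction_above(t)` sums the bins whose
lower edge is at or above a bin-boundary threshold.

## Synthetic scenario generator

The generator emulates the statistical structure the analysis assumes, not
ocean dynamics:

* **SST** — each meridional column is piecewise linear: warming toward the
  far equatorward side at 1 °C/100 km (the opposite flank of the cold
  tongue), a V-minimum at the front base latitude (default 20 °C), a linear
  rise of 6 °C over the 300 km frontal width, then a 0.5 °C/1000 km
  background gradient. The base latitude meanders as
  `A sin(2πx/λ − 2πt/P)` (defaults A = 150 km, λ = 1000 km, P = 25 d, the
  scales of tropical-instability-wave distortion), with an optional second
  harmonic for vortex-like shapes. Daily fields carry white noise of
  0.1 °C — the effective noise of a composited merged microwave/infrared
  product rather than a single retrieval. A coastal variant mirrors the
  structure zonally (minimum inshore, rise offshore) with a seasonal
  warming trend.
* **Currents** — a westward jet centred on the front base with Gaussian
  meridional decay (core 1 m s⁻¹ westward, scale 200 km) plus white noise,
  on a 1/3°, 5-day grid.
* **Tracks** — per animal: *passive* (zonal advection by the nearest-node
  current), *front-biased* (zonal random walk plus daily meridional
  relaxation toward the latitude whose percent distance equals a per-animal
  target drawn from N(75 %, 15 %)), or *independent* (unbiased random walk).
  Fix emission follows a Poisson fixes-per-day rate with uniform times,
  location classes drawn from a configurable mix, per-class Gaussian errors
  (0.25–10 km), and optional gross outliers of 250–600 km emulating Argos
  failures. True midday positions and true analytic percent distances are
  emitted as a ground-truth channel consumed only by tests.
* **TAT** — the occupied-temperature series (SST sampled along the true
  track) binned into the tag's 12-h windows.

Default sizes mirror the tracked population the data structure emulates
(27 animals, ~2-month durations, a handful of positions per day); evaluation
experiments override sizes explicitly (e.g. 1000 short tracks for the
occupancy-recovery experiment, 100 replicates of 500 matchup pairs for the
independence null) to keep each experiment under a few minutes on one core.

What the generator does **not** emulate: cloud masking and retrieval gaps,
land, eddy kinematics beyond the sinusoidal meander, diel behaviour,
subsurface temperature structure (TAT series sample surface temperature
only), and current fields inconsistent with the front position. Passing
recovery tests therefore demonstrate correctness of the analysis chain under
the stated statistical structure, not robustness to every artefact of real
satellite products.

## Numerical choices and degenerate inputs

* Ties everywhere are deterministic: earlier timestamp (filter removal,
  daily selection), earlier composite (time matching), lower index (nearest
  node).
* The filter raises once a tag's interior is exhausted rather than silently
  returning an empty track.
* Sections whose anchor falls on a masked cell raise; sections clipped by
  the domain or mask are flagged `short_section` when either side is under
  300 km.
* All randomness derives from a single scenario seed via independent named
  streams; identical config and seed give bit-identical files, and the
  pipeline writes no timestamps or absolute paths into artifacts, so full
  reruns are byte-identical.
* Percent distances are undefined (`NaN`, flagged) when no front is found;
  aggregates exclude and count them.

## Known limitations

* The slope-break definition is inherently a formalisation of a visual
  feature; profiles whose background gradient approaches the frontal
  gradient (fronts without a distinct break) are flagged rather than forced.
* The hinge refinement assumes locally piecewise-linear structure; strongly
  curved fronts would be localised by the coarse stage alone, with its
  half-window bias.
* Matchup currents are taken at a single nearest node, following the
  analysis convention, so sub-grid current shear contributes irreducible
  scatter to r².
* The coastal variant shares one code path with the equatorial analysis by
  construction; it has not been exercised against real eastern-boundary
  fields.
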