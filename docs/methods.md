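# Methods

This note documents the models, conventions and numerical choices behind
`cyclepm`, and what the synthetic-campaign tests do and do not demonstrate
about real data.

## Problem setting

Bicycle-mounted optical PM2.5 sensors sample every 10 s while moving and
report GPS position alongside the reading. Three facts shape the analysis:
(i) low-cost optical sensors carry multiplicative errors (device gain,
humidity response) that drift too much for one-off factory calibration;
(ii) a trip's concentration profile mixes a slowly varying regional
background with short, local traffic plumes; (iii) with many participants,
some kits malfunction or are misused (indoor use, transport on vehicles)
and must be screened out statistically.

## Quality control

Applied in a fixed order: speed window → device screening → trip trimming
→ minimum points. Order matters: device means are computed on speed-valid
points only, and trimming is applied before the minimum-point rule.

- **Speed window** [5, 45] km/h, bounds inclusive. Point speeds come from
  consecutive same-device GPS fixes (haversine distance / Δt; the first
  point of a stream inherits its successor's speed). The lower bound
  removes stationary and indoor use, the upper bound motorised transport.
- **Device screening.** A device is excluded as `flat_low` when its
  campaign mean is below 3 µg/m³ (covered inlets report near-zero), and as
  `high_outlier` when its mean exceeds 3× the across-station official mean
  over its own active hours. The factor 3 generalises from observed
  malfunction cases, where credible kits sat well below 3× the regional
  level and bad kits at 4× and beyond; it is configurable
  (`QCParams.high_ratio`).
- **Trimming.** floor(0.05·n) points off each trip end; optical sensors
  need minutes to equilibrate after indoor–outdoor transfer. Rounding down
  is our convention (a 10-point trip is untouched).
- **Minimum points**: 25 by default (≈ 4 min of data); 50 is used as a
  sensitivity variant.

Trips are segmented at inter-record gaps > 120 s (12 missed samples).
Stops at traffic lights are filtered by speed, not by gap, so they do not
split trips; the threshold is configurable.

## Hourly ratio calibration

For hour h, with stations s that have both an official value C_LML(s, h)
and a sensor mean C̄_sens(s, h) — the mean over all co-located and passing
sensor values within 1 km of the station, requiring ≥ 6 values
(one minute of data; our choice) —

    β(h) = (1/n) Σ_s C_LML(s, h) / C̄_sens(s, h)

applied multiplicatively to every mobile record of the hour. Guard rails
run in sequence: stations with a zero sensor mean are skipped (n
decremented); if n < 2 the area-wide factor is not identifiable and β = 1;
β is clamped into [0.5, 5.0]; and when the pooled sensor mean exceeds
15 µg/m³, the correction is only applied when official stations agree
(sample SD < 0.15 × mean), because one area-wide factor is otherwise not
representative. The pooled (not per-station) sensor mean is used in this
last guard since the guard asks an area-wide question. Hours with a guard
fallback keep β = 1 rather than dropping data; hours with no factor at all
get β = 1 and an `UNCALIBRATED_HOUR` flag. A sensor inside two stations'
radii contributes to both — intentional, matching how closely spaced
urban stations share co-located kits.

**Calibration input.** The stationary co-located kits that anchor β would
be removed by the 5–45 km/h window. The calibration pool is therefore all
position-valid records of devices that passed screening (devices excluded
as `flat_low`/`high_outlier` never calibrate; devices with zero
speed-valid points remain in the pool), while the exposure chain uses the
fully speed-filtered points.

**Validation (LSO).** For each station, β is recomputed with that
station's official data left out and applied to the sensor series at the
station; raw and calibrated series are compared with the official series
via bias, MAE, RMSE and Pearson correlation (undefined for constant
series and reported as missing, not 0). The difference SD uses ddof = 1,
and the 95% CI convention is 2·SD (not 1.96·SD), matching the reporting
convention of the field campaign this package is built around. Report
summaries are unweighted column means across stations.

## Traffic increments

Background per trip = the linear-interpolation percentile (default 10%)
of the trip's calibrated concentrations. The minimum would be biased low
by sensor noise and warm-up; a low percentile is robust to both while
still falling in the traffic-free part of the profile, provided a part of
the trip is away from traffic — typically true because trips start and
end at homes and destinations off busy streets. Increments are **signed**
(points below the background get negative increments), so
mean_increment = mean_total − background holds exactly and no positive
bias is introduced; clamping at zero would inflate the mean.

The per-trip increment falls monotonically as the percentile rises; the
5/10/15% step (~0.5 µg/m³ on default synthetic campaigns) is treated as
the systematic uncertainty of the approach.

**Stable hours.** Hour h is unstable when |A(h) − A(h−1)| > 2.5 µg/m³,
where A is the across-station mean of official values (Δ of the mean, not
mean of |Δ| — the criterion asks about the regional background, not
single-station noise). The first hour of a series, or an hour without a
direct predecessor, is stable by convention. A trip overlaps an unstable
hour when any of its points falls in it; such trips are flagged and can
be excluded in sensitivity analyses.

Summaries report histograms in 0.25 µg/m³ bins and group means, pooled or
by calendar quarter (Jan–Mar … Oct–Dec) of the trip start.

## Spatial aggregation

Geographic coordinates are projected to Dutch RD New (EPSG:28992) metres
with a self-contained implementation of the published polynomial
approximation to the official transformation (decimetre accuracy in the
Netherlands; round-trip error < 1 mm over the study domain — negligible
against 25 m cells). Cells are half-open: i = floor((x − x₀)/size).

- **Exposure grid**: 25 m cells; per cell the count, distinct-device count
  and mean signed increment. A cell is reported only with ≥ 15
  observations from ≥ 3 devices — a small-count suppression rule against
  single-rider artefacts. Reported cells are classified into 5 quantile
  classes (linear-interpolation quantile breaks over reported cell means,
  not raw values; ties collapse to the lowest containing class, so an
  all-tied layer is entirely class 1). Output: GeoJSON polygons (WGS84)
  plus a full CSV including suppressed cells.
- **Co-incidence diagnostic**: 50 m cells × hour with ≥ 2 devices; the
  sample SD of per-device means, relative to the mean of those means,
  estimates between-device precision under field conditions. Computed on
  calibrated values.

## Synthetic campaigns

The generator emulates the study conditions the pipeline is designed for,
in planar metres on a 20 × 20 km square written out as WGS84 via the RD
projection (inverse-projected, so the geographic ingest path is genuinely
exercised):

- **Background** B(t): hourly lognormal AR(1); defaults mean 9.9 µg/m³,
  σ_log 0.35, AR coefficient 0.95 — giving the familiar lognormal annual
  distribution and hour-to-hour changes that put a few percent of hours
  above the 2.5 µg/m³ stability threshold. Point-level values are
  linearly interpolated between hour centres: real backgrounds drift
  smoothly, and hourly steps would inject artificial within-trip jumps
  into the percentile background. Station series report the hourly value
  plus N(0, 0.3) instrument noise.
- **Traffic field** T(x) = T₀·exp(−d(x)/λ) with distance d to the nearest
  road; defaults T₀ = 2.7 µg/m³, λ = 60 m, a near-road increment scale of
  order 2 µg/m³ decaying within tens of metres. Constant in time: no
  rush-hour dynamics, by design.
- **Trips** connect a pool of 12 shared "places" (homes, offices,
  schools) clustered into 3 towns, each at the end of a fixed off-road
  corridor (perpendicular ~400 m, then parallel to the road); the on-road
  part follows the deterministic Manhattan route between anchors on a
  1 km road grid. Shared places both mirror how real exposure maps emerge
  (many riders on common corridors) and guarantee, by construction, that
  15–25% of each trip at either end is off-road when the
  `offroad_start_prob` = 0.8 coin lands that way — enough that the 10th
  percentile falls on traffic-free points even after 5% trimming. Place
  pairs are chosen to match a Gamma(4)-drawn target duration (mean
  17 min) at a cruising speed drawn from 10–25 km/h (the QC window is
  wider, 5–45; the generator default is a realistic cycling range).
  Poisson(0.4) trips per device-day, start times 07:00–20:00.
- **Sensor model**: raw = g_d · (1 + 0.003·(RH − 50)) · (B + T) + N(0, 1)
  per 10-s sample, clipped at zero; RH follows a diurnal sinusoid
  50 ± 20%. Device gains are mean-corrected lognormal (sd 0.10). The
  humidity term is a stand-in: the real sensor response to humidity is
  not characterised beyond its correlation with the official/sensor
  ratio, and a multiplicative form is exactly what an hourly ratio
  correction can remove. Device roles are assigned by a seeded shuffle
  with exact counts — 15% flat-low kits (gain × 0.15, campaign mean
  < 3 µg/m³) and 5% high-biased kits (gain 4) by default.
- **Co-located kits**: one stationary device per station, sampling every
  60 s, same error model; they anchor the calibration exactly as real
  co-located kits do and are screened out of the mobile chain by the
  speed filter.
- **Truth ledger**: per point the true T(x) and interpolated B(t); per
  trip the mean of its points' T. Every emitted record appears exactly
  once.

Defaults were fixed once so that the generated conditions state the
intended study: mean trip duration ≈ 17 min, true mean trip increment
2.0 µg/m³, background mean 9.9 µg/m³.

**What passing tests show — and what they don't.** Recovery within
±0.5 µg/m³ on these campaigns demonstrates that the pipeline's estimator
chain is unbiased under its own assumptions (smooth background,
exponential near-road decay, multiplicative sensor error, trips with
traffic-free stretches). Real data add unmodelled effects — wind-driven
plume asymmetry, temporally varying emissions, GPS multipath, sensor
aging, non-multiplicative humidity artefacts at fog — so field accuracy
is expected to be worse than the synthetic recovery error. User-supplied
road GeoJSON feeds the traffic field; trip synthesis itself requires the
rectilinear default network.

## Numerical conventions

- Percentile and quantile computations use NumPy's linear-interpolation
  definition throughout.
- Sample (ddof = 1) standard deviations everywhere a spread across
  stations or devices is reported.
- Degenerate inputs: empty trips are errors at the percentile level and
  skipped at the pipeline level; station-hours with < 6 sensor values are
  absent (not zero); Pearson of a constant series is missing (not 0);
  empty summary groups are absent (not zero).
- Hour bucketing is floor-to-hour in UTC; timestamps are parsed as UTC
  throughout (the input dialect carries Z-suffixed ISO 8601).
- Problem sizes in the test suite and acceptance script (20 devices ×
  30 days for the default campaign; 8 × 7 for replicate studies) are
  chosen so every ground-truth recovery has > 100 trips and > 100
  reported cells while a full run stays in seconds — the same statistics
  at one-thousandth of the real campaign's record count.

## Known limitations

- The high-outlier screening ratio (3×) generalises a judgment call made
  on a single observed device; treat borderline devices with care.
- The ratio calibration corrects area-wide multiplicative error only;
  per-device offsets and aging are out of scope (as in the field study).
- No dispersion modelling, route planning, health-impact conversion, or
  cartographic rendering; the classified GeoJSON cell layer is the map
  deliverable.
- The RD projection limits metric gridding to the Netherlands-sized
  domain it is defined on; other regions need a different planar CRS,
  which `GridSpec` deliberately refuses rather than silently accepting.
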