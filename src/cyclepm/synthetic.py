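"""Synthetic mobile PM2.5 campaign generator with known ground truth.

Emulates a bicycle sensor campaign in a Dutch-style study area: a lognormal
AR(1) regional background, near-road traffic increments that decay
exponentially with distance to the road, reference stations reporting hourly
background values, stationary sensor kits co-located at those stations, and
bicycle trips sampled every 10 s along a rectilinear road network.  Sensor
error is multiplicative (per-device gain and a relative-humidity term) plus
additive 10-s noise; a configurable fraction of devices malfunction
(flat-low or high-biased).  Every emitted record is paired with its true
traffic increment in a truth ledger so the downstream pipeline can be tested
for recovery of known quantities.

All coordinates are generated in planar metres and written as WGS84 lat/lon
through the RD New projection, so the geographic ingest path is exercised.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .projection import rd_to_wgs84

__all__ = [
    "CampaignConfig",
    "SyntheticTruth",
    "Campaign",
    "ConfigError",
    "generate_background",
    "generate_roads",
    "traffic_field",
    "generate_campaign",
    "write_campaign",
]


class ConfigError(ValueError):
    """Raised when a campaign configuration violates its invariants."""


@dataclass(frozen=True)
class CampaignConfig:
    """Study conditions for one synthetic campaign.

    Defaults mirror the 2020 Utrecht-province conditions the pipeline is
    designed for: annual-mean background near 9.9 ug/m3 with a lognormal
    hourly distribution, traffic increments of order 2 ug/m3 at the road
    decaying over tens of metres, 10-s sampling, trips averaging 17 minutes,
    and roughly one fifth of devices misbehaving.
    """

    seed: int = 0
    n_devices: int = 20
    n_days: int = 30
    start_date: str = "2020-01-01"
    background_mean: float = 9.9          # ug/m3, long-run mean of B(t)
    background_sigma_log: float = 0.35    # sd of log background
    ar1_coef: float = 0.95                # hourly log-AR(1) coefficient
    traffic_peak: float = 2.7             # T0, ug/m3 on the road axis
    traffic_decay_length: float = 60.0    # lambda, metres
    device_gain_mean: float = 1.0
    device_gain_sd: float = 0.10          # sd of log gain across devices
    rh_gain_slope: float = 0.003          # multiplicative, per %RH about 50%
    noise_sd_10s: float = 1.0             # additive ug/m3 per 10-s sample
    frac_flatlow_devices: float = 0.15
    frac_highbias_devices: float = 0.05
    trip_rate_per_device_day: float = 0.4
    mean_trip_minutes: float = 17.0
    speed_range: tuple[float, float] = (10.0, 25.0)   # km/h, cruising range
    station_locations: tuple[tuple[float, float], ...] = (
        (4300.0, 4400.0), (4700.0, 4600.0),
        (12400.0, 15400.0), (16400.0, 6600.0),
    )
    station_noise_sd: float = 0.3         # ug/m3 on hourly reference values
    sample_period: float = 10.0           # seconds between mobile samples
    road_spacing_m: float = 1000.0
    area_size_m: float = 20000.0
    offroad_start_prob: float = 0.8
    n_places: int = 12                    # shared trip origins/destinations
    place_depth_m: float = 400.0          # off-road corridor depth
    n_towns: int = 3                      # clusters of places (urban centres)
    town_radius_m: float = 2500.0
    n_colocated_per_station: int = 1
    colocated_period_s: float = 60.0
    flatlow_gain: float = 0.15            # extra factor for flat-low devices
    highbias_gain: float = 4.0            # replacement gain for biased devices
    rd_origin: tuple[float, float] = (125000.0, 440000.0)

    def validate(self) -> None:
        c = self
        if c.n_devices < 1 or c.n_days < 1:
            raise ConfigError("n_devices and n_days must be >= 1")
        if c.background_mean <= 0:
            raise ConfigError("background_mean must be positive")
        if c.traffic_decay_length <= 0:
            raise ConfigError("traffic_decay_length must be positive")
        for name in ("background_sigma_log", "device_gain_sd", "noise_sd_10s",
                     "station_noise_sd", "trip_rate_per_device_day",
                     "frac_flatlow_devices", "frac_highbias_devices",
                     "traffic_peak"):
            if getattr(c, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not (0.0 <= c.ar1_coef < 1.0):
            raise ConfigError("ar1_coef must lie in [0, 1)")
        lo, hi = c.speed_range
        if not (0.0 < lo <= hi <= 45.0):
            raise ConfigError("speed_range must lie within (0, 45] km/h")
        if c.frac_flatlow_devices + c.frac_highbias_devices > 1.0:
            raise ConfigError("malfunction fractions must sum to <= 1")
        if c.sample_period <= 0 or c.colocated_period_s <= 0:
            raise ConfigError("sampling periods must be positive")

    def replace(self, **kw) -> "CampaignConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for one synthetic campaign.

    ``points`` has one row per emitted measurement (index = point_id) with
    the true traffic increment, the true background and the generator trip
    id ('' for stationary co-located kits).  ``per_trip_true_increment`` is
    the mean of the per-point truth over each trip's points.
    """

    background_series: pd.Series           # hourly B(t), ug/m3
    device_gain: pd.Series                 # effective gain per device
    points: pd.DataFrame                   # per-point truth ledger
    per_trip_true_increment: pd.Series     # ug/m3 per trip id

    @property
    def per_point_true_increment(self) -> pd.Series:
        return self.points["true_increment"]


@dataclass
class Campaign:
    config: CampaignConfig
    measurements: pd.DataFrame   # ingest dialect columns, index = point_id
    stations: pd.DataFrame       # station_id, lat, lon, hour, pm25
    roads: shapely.MultiLineString
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# background and traffic field


def generate_background(config: CampaignConfig,
                        rng: np.random.Generator | None = None) -> pd.Series:
    """Hourly regional background series B(t) over the campaign.

    log B follows a stationary Gaussian AR(1) with marginal sd
    ``background_sigma_log``; the log-mean is offset by -sigma^2/2 so the
    series mean converges to ``background_mean``.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    n = 24 * config.n_days
    sig = config.background_sigma_log
    phi = config.ar1_coef
    z = np.zeros(n)
    if sig > 0:
        eps_sd = sig * np.sqrt(1.0 - phi**2)
        z[0] = rng.normal(0.0, sig)
        shocks = rng.normal(0.0, eps_sd, n - 1)
        for i in range(1, n):
            z[i] = phi * z[i - 1] + shocks[i - 1]
    else:
        # keep the stream position independent of sigma
        rng.normal(size=n)
    mu = np.log(config.background_mean) - 0.5 * sig**2
    values = np.exp(mu + z)
    hours = pd.date_range(config.start_date, periods=n, freq="h", tz="UTC")
    return pd.Series(values, index=hours, name="background")


def generate_roads(config: CampaignConfig,
                   geojson_path: str | Path | None = None) -> shapely.MultiLineString:
    """Road polylines in planar campaign metres.

    By default a rectilinear grid with ``road_spacing_m`` spacing over the
    square study area; alternatively read LineStrings from a GeoJSON file
    whose coordinates are already planar campaign metres.
    """
    if geojson_path is not None:
        gj = json.loads(Path(geojson_path).read_text())
        lines = []
        feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
        for f in feats:
            geom = f.get("geometry", f)
            if geom["type"] == "LineString":
                lines.append(shapely.LineString(geom["coordinates"]))
            elif geom["type"] == "MultiLineString":
                lines.extend(shapely.LineString(c) for c in geom["coordinates"])
        if not lines:
            raise ConfigError("road GeoJSON contains no LineString features")
        return shapely.MultiLineString(lines)
    a = config.area_size_m
    s = config.road_spacing_m
    ticks = np.arange(0.0, a + 0.5 * s, s)
    lines = [shapely.LineString([(t, 0.0), (t, a)]) for t in ticks]
    lines += [shapely.LineString([(0.0, t), (a, t)]) for t in ticks]
    return shapely.MultiLineString(lines)


def traffic_field(config: CampaignConfig, roads: shapely.MultiLineString):
    """Deterministic traffic-increment field T(x) = T0 * exp(-d(x)/lambda).

    ``d(x)`` is the planar distance from x to the nearest road.  Returns a
    vectorized callable on planar metre coordinates.
    """
    if config.traffic_decay_length <= 0:
        raise ConfigError("traffic_decay_length must be positive")
    t0 = config.traffic_peak
    lam = config.traffic_decay_length

    def field(x, y):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if t0 == 0.0:
            return np.zeros(x.shape)
        pts = shapely.points(x, y)
        d = shapely.distance(pts, roads)
        return t0 * np.exp(-d / lam)

    return field


# ---------------------------------------------------------------------------
# trip geometry
#
# Trips connect a finite pool of "places" (homes, schools, offices): each
# place sits at the end of a fixed off-road corridor attached to an anchor
# point on the road grid, and the on-road part follows the deterministic
# Manhattan route between the two anchors.  A finite place pool makes
# different riders share corridors and road stretches, which is what lets
# grid cells accumulate observations from several devices -- the same
# mechanism that produces exposure maps in a real campaign.


@dataclass(frozen=True)
class _Place:
    anchor: tuple[float, float]   # on a road line
    on_vertical: bool             # orientation of the anchor road
    side: float                   # +-1, perpendicular corridor direction
    dirp: float                   # +-1, direction of the parallel extension
    depth: float                  # metres, perpendicular corridor depth


def _draw_places(rng, config: CampaignConfig) -> list[_Place]:
    """Trip origin/destination pool, clustered into a few urban centres.

    Clustering keeps typical place-to-place road distances at commuting
    scale and concentrates traffic on shared corridors.
    """
    a = config.area_size_m
    s = config.road_spacing_m
    centres = rng.uniform(0.3 * a, 0.7 * a, size=(max(config.n_towns, 1), 2))
    places = []
    for _ in range(config.n_places):
        c = centres[int(rng.integers(len(centres)))]
        px, py = c + rng.uniform(-config.town_radius_m, config.town_radius_m, 2)
        px = float(np.clip(px, 2.0 * s, a - 2.0 * s))
        py = float(np.clip(py, 2.0 * s, a - 2.0 * s))
        on_vertical = bool(rng.random() < 0.5)
        if on_vertical:
            k = float(np.clip(np.round(px / s), 2, a / s - 2)) * s
            anchor, along = (k, py), py
        else:
            k = float(np.clip(np.round(py / s), 2, a / s - 2)) * s
            anchor, along = (px, k), px
        # corridor and extension point towards the area centre so long
        # trips stay inside the study square
        perp_coord = anchor[0] if on_vertical else anchor[1]
        par_coord = anchor[1] if on_vertical else anchor[0]
        side = 1.0 if perp_coord < a / 2 else -1.0
        dirp = 1.0 if par_coord < a / 2 else -1.0
        depth = float(rng.uniform(0.75, 1.15) * config.place_depth_m)
        places.append(_Place(anchor, on_vertical, side, dirp, depth))
    return places


def _corridor_leg(place: _Place, length: float) -> list[tuple[float, float]]:
    """Waypoints of a place's off-road corridor, outward from the anchor.

    First perpendicular to the anchor road up to the place depth, then
    parallel to it; the parallel stretch crosses other roads transversally
    but never runs along one, so most of the corridor sits in
    near-zero-traffic territory.
    """
    ax, ay = place.anchor
    d = min(length, place.depth)
    l_par = max(length - place.depth, 0.0)
    if place.on_vertical:
        pts = [(ax + place.side * d, ay)]
        if l_par > 0:
            pts.append((ax + place.side * d, ay + place.dirp * l_par))
    else:
        pts = [(ax, ay + place.side * d)]
        if l_par > 0:
            pts.append((ax + place.dirp * l_par, ay + place.side * d))
    return pts


def _road_route(a: _Place, b: _Place, spacing: float) -> list[tuple[float, float]]:
    """Deterministic Manhattan route along grid roads between two anchors."""
    (ax, ay), (bx, by) = a.anchor, b.anchor

    def to_grid(p, on_vertical, towards):
        # nearest intersection on the anchor's road, towards the other anchor
        x, y = p
        if on_vertical:
            g = np.floor(y / spacing) * spacing if towards[1] < y \
                else np.ceil(y / spacing) * spacing
            return (x, float(g))
        g = np.floor(x / spacing) * spacing if towards[0] < x \
            else np.ceil(x / spacing) * spacing
        return (float(g), y)

    ia = to_grid(a.anchor, a.on_vertical, b.anchor)
    ib = to_grid(b.anchor, b.on_vertical, a.anchor)
    elbow = (ib[0], ia[1])   # x-first
    pts = [(ax, ay), ia, elbow, ib, (bx, by)]
    out = [pts[0]]
    for p in pts[1:]:
        if p != out[-1]:
            out.append(p)
    return out


def _route_length(pts) -> float:
    arr = np.asarray(pts, dtype=float)
    if len(arr) < 2:
        return 0.0
    seg = np.diff(arr, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def _sample_path(path: np.ndarray, speeds_ms: np.ndarray) -> np.ndarray:
    """Positions along ``path`` at cumulative per-sample travel distances."""
    seg = np.diff(path, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    dist = np.concatenate([[0.0], np.cumsum(speeds_ms)])
    dist = np.clip(dist, 0.0, cum[-1])
    x = np.interp(dist, cum, path[:, 0])
    y = np.interp(dist, cum, path[:, 1])
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# campaign assembly


def _diurnal_rh(hours_of_day: np.ndarray) -> np.ndarray:
    # smooth diurnal cycle, 50 +/- 20 %RH, driest mid-afternoon
    return 50.0 - 20.0 * np.sin(2.0 * np.pi * (hours_of_day - 9.0) / 24.0)


def _diurnal_temp(hours_of_day: np.ndarray) -> np.ndarray:
    return 11.0 + 5.0 * np.sin(2.0 * np.pi * (hours_of_day - 9.0) / 24.0)


def _device_roles(rng, config: CampaignConfig) -> pd.DataFrame:
    """Deterministic role assignment: exact malfunction counts per fraction."""
    n = config.n_devices
    ids = [f"bike-{i:03d}" for i in range(n)]
    n_flat = int(np.floor(config.frac_flatlow_devices * n + 0.5))
    n_high = int(np.floor(config.frac_highbias_devices * n + 0.5))
    roles = np.array(["normal"] * n, dtype=object)
    order = rng.permutation(n)
    roles[order[:n_flat]] = "flat_low"
    roles[order[n_flat:n_flat + n_high]] = "high_bias"
    return pd.DataFrame({"device_id": ids, "role": roles}).set_index("device_id")


def generate_campaign(config: CampaignConfig,
                      roads: shapely.MultiLineString | None = None) -> Campaign:
    """Generate a full synthetic campaign (measurements, stations, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    background = generate_background(config, rng)
    if roads is None:
        roads = generate_roads(config)
    field_fn = traffic_field(config, roads)
    t0_ns = background.index[0].value
    hour_values = background.to_numpy()

    roles = _device_roles(rng, config)
    gain_sd = config.device_gain_sd
    log_gain = rng.normal(0.0, gain_sd, config.n_devices) if gain_sd > 0 else \
        np.zeros(config.n_devices)
    base_gain = config.device_gain_mean * np.exp(log_gain - 0.5 * gain_sd**2)
    gain = base_gain.copy()
    gain[roles["role"].to_numpy() == "flat_low"] *= config.flatlow_gain
    gain[roles["role"].to_numpy() == "high_bias"] = config.highbias_gain
    device_gain = pd.Series(gain, index=roles.index, name="gain")

    frames = []      # per-point records

    dt = config.sample_period
    day_seconds = 86400.0
    mean_trip_s = config.mean_trip_minutes * 60.0

    places = _draw_places(rng, config)
    n_places = len(places)
    routes = {}
    dist = np.zeros((n_places, n_places))
    for i in range(n_places):
        for j in range(n_places):
            if i == j:
                continue
            routes[i, j] = _road_route(places[i], places[j],
                                       config.road_spacing_m)
            dist[i, j] = _route_length(routes[i, j])

    for device in roles.index:
        trip_no = 0
        for day in range(config.n_days):
            n_trips = rng.poisson(config.trip_rate_per_device_day)
            if n_trips == 0:
                continue
            starts = np.sort(rng.uniform(7.0, 20.0, n_trips)) * 3600.0
            last_end = -np.inf
            for st in starts:
                dur_target = float(np.clip(rng.gamma(4.0, mean_trip_s / 4.0),
                                           5 * 60.0, 60 * 60.0))
                v_kmh = rng.uniform(*config.speed_range)
                v_ms = v_kmh / 3.6
                f_in = (rng.uniform(0.15, 0.25)
                        if rng.random() < config.offroad_start_prob else 0.0)
                f_out = (rng.uniform(0.15, 0.25)
                         if rng.random() < config.offroad_start_prob else 0.0)
                on_road = 1.0 - f_in - f_out
                # pick the place pair whose road distance best matches the
                # drawn duration at the drawn speed
                pi = int(rng.integers(n_places))
                d_target = v_ms * dur_target * on_road
                cand = np.abs(dist[pi] - d_target)
                cand[pi] = np.inf
                qi = int(np.argmin(cand))
                length = dist[pi, qi] / on_road
                dur = length / v_ms
                if st < last_end + 600.0:   # keep trips separated
                    continue
                last_end = st + dur
                leg_in = _corridor_leg(places[pi], f_in * length)
                leg_out = _corridor_leg(places[qi], f_out * length)
                pts = list(reversed(leg_in)) + routes[pi, qi] + leg_out
                path = np.asarray(pts, dtype=float)
                n_pts = max(int(dur / dt), 2)
                step = np.full(n_pts - 1, v_ms * dt)
                pos = _sample_path(path, step)
                t_off = day * day_seconds + st + dt * np.arange(n_pts)
                trip_id = f"{device}-t{trip_no:04d}"
                trip_no += 1
                frames.append(pd.DataFrame({
                    "device_id": device,
                    "t_off": t_off,
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                    "trip_id": trip_id,
                }))

    # stationary co-located kits at each station
    n_colo = config.n_colocated_per_station
    colo_ids = []
    colo_gains = []
    total_s = config.n_days * day_seconds
    t_colo = np.arange(0.0, total_s, config.colocated_period_s)
    for si, (sx, sy) in enumerate(config.station_locations):
        for k in range(n_colo):
            cid = f"colo-{si:02d}-{k}"
            colo_ids.append(cid)
            lg = rng.normal(0.0, gain_sd) if gain_sd > 0 else 0.0
            colo_gains.append(config.device_gain_mean *
                              np.exp(lg - 0.5 * gain_sd**2))
            frames.append(pd.DataFrame({
                "device_id": cid,
                "t_off": t_colo,
                "x": sx + 3.0 * k,
                "y": sy,
                "trip_id": "",
            }))
    if colo_ids:
        device_gain = pd.concat([
            device_gain,
            pd.Series(colo_gains, index=pd.Index(colo_ids, name="device_id"),
                      name="gain"),
        ])

    if frames:
        pts = pd.concat(frames, ignore_index=True)
    else:
        raise ConfigError("campaign produced no measurements; raise the trip rate")
    pts.sort_values(["device_id", "t_off"], kind="mergesort",
                    ignore_index=True, inplace=True)

    # instantaneous background: linear interpolation between hour centres
    # (the hourly series represents hour averages; real backgrounds drift
    # smoothly rather than stepping at hour boundaries)
    t_hours = pts["t_off"].to_numpy() / 3600.0
    b = np.interp(t_hours, np.arange(len(hour_values)) + 0.5, hour_values)
    t_inc = field_fn(pts["x"].to_numpy(), pts["y"].to_numpy())
    hod = (pts["t_off"].to_numpy() % day_seconds) / 3600.0
    rh = _diurnal_rh(hod)
    temp = _diurnal_temp(hod)
    g = device_gain.reindex(pts["device_id"]).to_numpy()
    noise = (rng.normal(0.0, config.noise_sd_10s, len(pts))
             if config.noise_sd_10s > 0 else np.zeros(len(pts)))
    raw = g * (1.0 + config.rh_gain_slope * (rh - 50.0)) * (b + t_inc) + noise
    raw = np.maximum(raw, 0.0)

    origin = np.asarray(config.rd_origin)
    lat, lon = rd_to_wgs84(pts["x"].to_numpy() + origin[0],
                           pts["y"].to_numpy() + origin[1])
    time = pd.to_datetime(t0_ns + (pts["t_off"].to_numpy() * 1e9).astype("int64"),
                          utc=True)

    measurements = pd.DataFrame({
        "device_id": pts["device_id"],
        "time": time,
        "lat": np.round(lat, 7),
        "lon": np.round(lon, 7),
        "pm25_raw": np.round(raw, 3),
        "rh": np.round(rh, 2),
        "temp": np.round(temp, 2),
    })
    measurements.index.name = "point_id"

    truth_points = pd.DataFrame({
        "device_id": pts["device_id"],
        "time": time,
        "trip_id": pts["trip_id"],
        "x": pts["x"],
        "y": pts["y"],
        "true_increment": t_inc,
        "true_background": b,
    })
    truth_points.index.name = "point_id"
    on_trip = truth_points["trip_id"] != ""
    per_trip = (truth_points.loc[on_trip]
                .groupby("trip_id")["true_increment"].mean())
    per_trip.name = "true_increment"

    # hourly reference-station series
    st_rows = []
    hours = background.index
    for si, (sx, sy) in enumerate(config.station_locations):
        slat, slon = rd_to_wgs84(sx + origin[0], sy + origin[1])
        noise_s = (rng.normal(0.0, config.station_noise_sd, len(hours))
                   if config.station_noise_sd > 0 else np.zeros(len(hours)))
        st_rows.append(pd.DataFrame({
            "station_id": f"station-{si:02d}",
            "lat": np.round(float(slat), 7),
            "lon": np.round(float(slon), 7),
            "hour": hours,
            "pm25": np.round(np.maximum(background.to_numpy() + noise_s, 0.0), 3),
        }))
    stations = pd.concat(st_rows, ignore_index=True)

    truth = SyntheticTruth(
        background_series=background,
        device_gain=device_gain,
        points=truth_points,
        per_trip_true_increment=per_trip,
    )
    return Campaign(config=config, measurements=measurements,
                    stations=stations, roads=roads, truth=truth)


# ---------------------------------------------------------------------------
# writers


def roads_to_geojson(roads: shapely.MultiLineString,
                     rd_origin: tuple[float, float]) -> dict:
    """Road polylines as a WGS84 GeoJSON FeatureCollection."""
    ox, oy = rd_origin
    feats = []
    for line in roads.geoms:
        xy = np.asarray(line.coords)
        lat, lon = rd_to_wgs84(xy[:, 0] + ox, xy[:, 1] + oy)
        coords = [[round(float(lo), 7), round(float(la), 7)]
                  for la, lo in zip(lat, lon)]
        feats.append({"type": "Feature", "properties": {},
                      "geometry": {"type": "LineString", "coordinates": coords}})
    return {"type": "FeatureCollection", "features": feats}


def write_campaign(campaign: Campaign, outdir: str | Path) -> dict[str, Path]:
    """Write a campaign to CSV/GeoJSON files in the ingest dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    m = campaign.measurements.copy()
    m["timestamp_iso8601"] = m["time"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    cols = ["device_id", "timestamp_iso8601", "lat", "lon", "pm25_raw", "rh", "temp"]
    paths["measurements"] = outdir / "measurements.csv"
    m[cols].to_csv(paths["measurements"], index=False)

    s = campaign.stations.copy()
    s["hour_start_iso8601"] = s["hour"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    scols = ["station_id", "lat", "lon", "hour_start_iso8601", "pm25"]
    paths["stations"] = outdir / "stations.csv"
    s[scols].to_csv(paths["stations"], index=False)

    paths["roads"] = outdir / "roads.geojson"
    paths["roads"].write_text(json.dumps(
        roads_to_geojson(campaign.roads, campaign.config.rd_origin)))

    t = campaign.truth
    paths["truth_points"] = outdir / "truth_points.csv"
    tp = t.points.copy()
    tp["time"] = tp["time"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    tp.to_csv(paths["truth_points"], index=True)
    paths["truth_trips"] = outdir / "truth_trips.csv"
    t.per_trip_true_increment.to_csv(paths["truth_trips"])
    paths["truth_background"] = outdir / "truth_background.csv"
    bg = t.background_series.copy()
    bg.index = bg.index.strftime("%Y-%m-%dT%H:%M:%SZ")
    bg.to_csv(paths["truth_background"], index_label="hour")
    paths["truth_devices"] = outdir / "truth_devices.csv"
    t.device_gain.to_csv(paths["truth_devices"])
    return paths
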