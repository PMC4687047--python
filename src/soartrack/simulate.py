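"""Ground-truthed synthetic GPS tracks of a central-place soaring forager.

The generator emits 1-Hz days with the behavioural phases the analysis
assumes: rest at the colony, outward commuting flight to a foraging
patch, a clumped low-altitude variable-speed foraging bout, and an inward
commuting flight home.  Commutes are either flapping (straight, constant
speed ~26.5 km/h, low altitude) or thermal-soaring (repeated climb-glide
cycles: a helical climb at a radiation-dependent climb rate followed by a
straight descending glide).  Thermal availability per commute is a
Bernoulli draw whose probability rises with solar radiation, emulating
the diurnal growth of convective uplift.  Gaussian position and altitude
noise and occasional low-quality fixes are applied after the geometry, so
the recorded ground truth (trip and bout boundaries, per-thermal ascent
and climb rate) is exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dem import DemGrid
from .geometry import inverse_local_xy, local_xy
from .tracking import Track
from .weather import RadiationSeries, make_radiation


@dataclass
class SimConfig:
    """Generator parameters; defaults describe the emulated study system.

    Behavioural rates mirror the field ranges: flapping cross-country
    speed ~26.5 km/h, climb speeds within 0.26–3.56 m/s, circling radius
    ~15–40 m, foraging trips a few km from the colony.
    """

    seed: int = 0
    colony_lon: float = -6.05
    colony_lat: float = 37.35
    colony_id: str = "SILO"
    individual_id: str = "KES01"
    colony_radius_m: float = 300.0
    date: str = "2012-06-15"
    n_trips: int = 4
    trip_start_hours: tuple | None = None   # UTC decimal hours; None = spread over day

    # commuting flight
    flap_speed_ms: float = 7.4          # ~26.5 km/h
    flap_agl_m: float = 20.0
    soar_climb_base_ms: float = 0.4
    soar_climb_rad_coeff: float = 0.0016  # m/s per Wh/m2 of radiation
    climb_jitter: tuple = (0.7, 1.4)    # per-thermal multiplicative range
    climb_clip_ms: tuple = (0.25, 3.5)
    circle_radius_m: float = 25.0
    circle_speed_ms: float = 8.0
    glide_ratio: float = 7.0
    glide_airspeed_ms: float = 9.0
    glide_floor_agl_m: float = 40.0
    thermal_top_agl_m: tuple = (140.0, 300.0)   # per-thermal draw range

    # foraging bout
    patch_distance_flap_m: float = 1300.0
    patch_distance_soar_m: float = 3500.0
    patch_distance_sigma: float = 0.25  # lognormal sigma around the mode mean
    bout_duration_s: float = 1800.0
    patch_radius_m: float = 100.0
    hover_speed_ms: float = 0.45
    dash_speed_ms: float = 7.5
    bout_agl_range_m: tuple = (3.0, 26.0)

    # thermal availability p(R) = pmin + (pmax - pmin) * logistic((R-c)/s)
    avail_pmin: float = 0.5
    avail_pmax: float = 0.95
    avail_center_wh: float = 400.0
    avail_scale_wh: float = 140.0

    # radiation day
    radiation_peak_wh: float = 950.0
    sunrise_hour: float = 5.0
    sunset_hour: float = 19.5

    # sampling and noise
    sampling_interval_s: float = 1.0
    sigma_xy_m: float = 3.0
    sigma_z_m: float = 4.0
    speed_noise_ms: float = 0.3
    bad_fix_prob: float = 0.002
    rest_pad_s: float = 300.0
    min_rest_s: float = 180.0
    base_elevation_m: float = 60.0
    full_day_rest: bool = False         # pad rest from sunrise to sunset

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthThermal:
    start: int
    end: int
    ascent_m: float
    climb_ms: float
    commute: str        # "outward" | "inward" | "standalone"
    trip: int = -1
    t_start: pd.Timestamp | None = None
    t_end: pd.Timestamp | None = None


@dataclass
class TruthTrip:
    start: int          # last fix inside colony radius before departure
    end: int            # first fix back inside
    event_start: int
    event_end: int
    outward_mode: str   # "flap" | "soar"
    inward_mode: str
    patch_distance_m: float
    t_start: pd.Timestamp | None = None
    t_end: pd.Timestamp | None = None


@dataclass
class GroundTruth:
    trips: list = field(default_factory=list)
    thermals: list = field(default_factory=list)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, pd.Timestamp):
                return o.isoformat()
            raise TypeError(type(o))
        return json.dumps({
            "trips": [dataclasses.asdict(t) for t in self.trips],
            "thermals": [dataclasses.asdict(t) for t in self.thermals],
        }, default=enc, indent=1)


def thermal_availability(radiation_wh: float, cfg: SimConfig) -> float:
    """Probability that a commute finds usable thermals, given radiation."""
    z = (radiation_wh - cfg.avail_center_wh) / cfg.avail_scale_wh
    return cfg.avail_pmin + (cfg.avail_pmax - cfg.avail_pmin) / (1.0 + np.exp(-z))


class _PathBuilder:
    """Accumulates 1-Hz planar samples (x, y, agl) with index bookkeeping."""

    def __init__(self, x0: float, y0: float, agl0: float):
        self.xs = [np.array([x0])]
        self.ys = [np.array([y0])]
        self.agls = [np.array([agl0])]
        self.n = 1

    @property
    def state(self) -> tuple[float, float, float]:
        return (float(self.xs[-1][-1]), float(self.ys[-1][-1]),
                float(self.agls[-1][-1]))

    def add(self, x: np.ndarray, y: np.ndarray, agl: np.ndarray) -> tuple[int, int]:
        """Append a segment; returns its inclusive index span."""
        if len(x) == 0:
            return (self.n - 1, self.n - 1)
        self.xs.append(np.asarray(x, float))
        self.ys.append(np.asarray(y, float))
        self.agls.append(np.asarray(agl, float))
        s = self.n
        self.n += len(x)
        return (s, self.n - 1)

    def arrays(self):
        return (np.concatenate(self.xs), np.concatenate(self.ys),
                np.concatenate(self.agls))


def _unit(dx: float, dy: float) -> tuple[float, float]:
    d = float(np.hypot(dx, dy))
    return (dx / d, dy / d) if d > 0 else (1.0, 0.0)


def _flap_leg(state, target, speed, agl_target, rng, max_len_m=None):
    x0, y0, agl0 = state
    ux, uy = _unit(target[0] - x0, target[1] - y0)
    dist = float(np.hypot(target[0] - x0, target[1] - y0))
    if max_len_m is not None:
        dist = min(dist, max_len_m)
    n = max(1, int(round(dist / speed)))
    t = np.arange(1, n + 1, dtype=float)
    # small lateral waviness and speed jitter keep the path lifelike
    lateral = 2.0 * np.sin(2 * np.pi * t / rng.uniform(25, 60) + rng.uniform(0, 6.28))
    along = t * speed
    x = x0 + ux * along - uy * lateral
    y = y0 + uy * along + ux * lateral
    agl = np.linspace(agl0, agl_target, n + 1)[1:] + \
        1.5 * np.sin(2 * np.pi * t / rng.uniform(30, 80))
    return x, y, agl


def _helix(state, r, direction, omega, climb, n, rng):
    """Circular climb: ``n`` seconds at angular speed ``omega`` (rad/s)."""
    x0, y0, agl0 = state
    phi0 = rng.uniform(0, 2 * np.pi)
    cx = x0 - r * np.cos(phi0)
    cy = y0 - r * np.sin(phi0)
    t = np.arange(1, n + 1, dtype=float)
    phi = phi0 + direction * omega * t
    x = cx + r * np.cos(phi)
    y = cy + r * np.sin(phi)
    agl = agl0 + climb * t
    return x, y, agl


def _glide(state, target, v, sink, floor):
    """Straight descending glide toward target until the altitude floor or
    arrival; returns the segment and whether the target was reached."""
    x0, y0, agl0 = state
    ux, uy = _unit(target[0] - x0, target[1] - y0)
    dist = float(np.hypot(target[0] - x0, target[1] - y0))
    n_alt = int((agl0 - floor) / sink) if agl0 > floor else 0
    n_dist = int(np.ceil(dist / v))
    n = max(1, min(n_alt, n_dist)) if n_alt > 0 else max(1, min(1, n_dist))
    reached = n >= n_dist
    t = np.arange(1, n + 1, dtype=float)
    x = x0 + ux * np.minimum(t * v, dist)
    y = y0 + uy * np.minimum(t * v, dist)
    agl = agl0 - sink * t
    return (x, y, agl), reached


def _spiral_down(state, r, omega, agl_target, rng):
    x0, y0, agl0 = state
    if agl0 <= agl_target:
        return np.array([]), np.array([]), np.array([])
    sink = 2.0
    n = max(1, int((agl0 - agl_target) / sink))
    return _helix(state, r, 1 if rng.random() < 0.5 else -1, omega,
                  -(agl0 - agl_target) / n, n, rng)


def _bout(state, center, radius, duration, cfg: SimConfig, rng):
    """Clumped foraging walk: alternating hover and dash, low AGL."""
    x0, y0, agl0 = state
    xs, ys, agls = [], [], []
    x, y, agl = x0, y0, agl0
    lo, hi = cfg.bout_agl_range_m
    t = 0
    while t < duration:
        hover = rng.random() < 0.65
        if hover:
            speed = max(0.05, rng.normal(cfg.hover_speed_ms, 0.15))
            dur = int(rng.uniform(4, 12))
        else:
            speed = rng.uniform(0.8, 1.2) * cfg.dash_speed_ms
            dur = int(rng.uniform(2, 6))
        ang = rng.uniform(0, 2 * np.pi)
        ux, uy = np.cos(ang), np.sin(ang)
        for _ in range(max(1, dur)):
            if t >= duration:
                break
            nx, ny = x + ux * speed, y + uy * speed
            if np.hypot(nx - center[0], ny - center[1]) > radius:
                ux, uy = _unit(center[0] - x, center[1] - y)
                nx, ny = x + ux * speed, y + uy * speed
            x, y = nx, ny
            agl = float(np.clip(agl + rng.normal(0, 0.8), lo, hi))
            xs.append(x)
            ys.append(y)
            agls.append(agl)
            t += 1
    return np.array(xs), np.array(ys), np.array(agls)


def _commute(builder: _PathBuilder, target, mode: str, cfg: SimConfig, rng,
             radiation: RadiationSeries, t_of_index, truth_thermals: list,
             commute_label: str, trip_index: int, final_agl: float):
    """Append one commuting flight ending near ``target`` at ``final_agl``."""
    if mode == "flap":
        x, y, agl = _flap_leg(builder.state, target, cfg.flap_speed_ms,
                              cfg.flap_agl_m, rng)
        # settle to the final altitude over the last stretch
        k = min(len(agl), 30)
        agl[-k:] = np.linspace(agl[-k], final_agl, k)
        builder.add(x, y, agl)
        return

    # soaring: initial flap-out, then climb-glide cycles
    dist0 = float(np.hypot(target[0] - builder.state[0], target[1] - builder.state[1]))
    x, y, agl = _flap_leg(builder.state, target, cfg.flap_speed_ms,
                          cfg.flap_agl_m, rng, max_len_m=min(400.0, 0.25 * dist0))
    builder.add(x, y, agl)
    omega = cfg.circle_speed_ms / cfg.circle_radius_m
    sink = cfg.glide_airspeed_ms / cfg.glide_ratio
    guard = 0
    while True:
        guard += 1
        if guard > 60:
            break
        sx, sy, sagl = builder.state
        remaining = float(np.hypot(target[0] - sx, target[1] - sy))
        # no thermalling on final approach: circling near the goal would
        # blur the commute/rest boundary (and, inbound, the colony radius)
        if remaining < 600.0:
            break
        # climb in a thermal
        r_wh = radiation.at(t_of_index(builder.n - 1))
        w = (cfg.soar_climb_base_ms + cfg.soar_climb_rad_coeff * r_wh) \
            * rng.uniform(*cfg.climb_jitter)
        w = float(np.clip(w, *cfg.climb_clip_ms))
        top = rng.uniform(*cfg.thermal_top_agl_m)
        n_climb = max(8, int(round((top - sagl) / w)))
        direction = 1 if rng.random() < 0.5 else -1
        x, y, agl = _helix(builder.state, cfg.circle_radius_m, direction,
                           omega, w, n_climb, rng)
        span = builder.add(x, y, agl)
        # truth uses the endpoint convention of the detector: ascent is the
        # AGL difference between the first and last in-thermal sample
        truth_thermals.append(TruthThermal(
            start=span[0], end=span[1],
            ascent_m=float(agl[-1] - agl[0]),
            climb_ms=w, commute=commute_label, trip=trip_index))
        # glide toward the goal
        seg, reached = _glide(builder.state, target, cfg.glide_airspeed_ms,
                              sink, cfg.glide_floor_agl_m)
        builder.add(*seg)
        if reached:
            break
    # descend over the goal, then close any remaining gap by flapping
    x, y, agl = _spiral_down(builder.state, cfg.circle_radius_m, omega,
                             max(final_agl, cfg.flap_agl_m), rng)
    builder.add(x, y, agl)
    sx, sy, _ = builder.state
    if np.hypot(target[0] - sx, target[1] - sy) > 1.5 * cfg.flap_speed_ms:
        x, y, agl = _flap_leg(builder.state, target, cfg.flap_speed_ms,
                              final_agl, rng)
        builder.add(x, y, agl)


def _rest(builder: _PathBuilder, duration_s: float, rng, agl: float = 10.0):
    n = int(duration_s)
    if n <= 0:
        return
    x0, y0, _ = builder.state
    x = np.clip(x0, -5, 5) + rng.normal(0, 1.5, n)
    y = np.clip(y0, -5, 5) + rng.normal(0, 1.5, n)
    builder.add(x, y, np.full(n, agl) + rng.normal(0, 0.5, n))


def _emit_track(cfg: SimConfig, x, y, agl, start_time: pd.Timestamp, rng) -> Track:
    """Apply observation noise and wrap planar truth into a Track."""
    n = len(x)
    xo = x + rng.normal(0, cfg.sigma_xy_m, n)
    yo = y + rng.normal(0, cfg.sigma_xy_m, n)
    lon, lat = inverse_local_xy(xo, yo, cfg.colony_lon, cfg.colony_lat)
    alt = cfg.base_elevation_m + agl + rng.normal(0, cfg.sigma_z_m, n)
    speed_true = np.hypot(np.diff(x), np.diff(y))
    speed = np.concatenate([speed_true[:1], speed_true]) + \
        np.abs(rng.normal(0, cfg.speed_noise_ms, n))
    nsat = rng.integers(5, 12, n).astype(float)
    dop = np.round(rng.uniform(0.8, 2.4, n), 2)
    bad = rng.random(n) < cfg.bad_fix_prob
    which = rng.random(n) < 0.5
    nsat[bad & which] = 3
    dop[bad & ~which] = 3.5
    times = start_time + pd.to_timedelta(np.arange(n), unit="s")
    fixes = pd.DataFrame({
        "timestamp": times, "lon": lon, "lat": lat, "gps_altitude": alt,
        "speed": speed, "n_satellites": nsat, "dop": dop, "agl": np.nan,
    })
    return Track(cfg.individual_id, fixes, cfg.sampling_interval_s,
                 colony_id=cfg.colony_id)


def _day_radiation(cfg: SimConfig) -> RadiationSeries:
    day = pd.Timestamp(cfg.date)
    rise = day + pd.Timedelta(hours=cfg.sunrise_hour)
    sett = day + pd.Timedelta(hours=cfg.sunset_hour)
    return make_radiation(day, cfg.radiation_peak_wh, rise, sett)


def _draw_patch(cfg: SimConfig, mode: str, rng) -> float:
    mean = cfg.patch_distance_soar_m if mode == "soar" else cfg.patch_distance_flap_m
    return float(mean * rng.lognormal(0.0, cfg.patch_distance_sigma))


def simulate_day(cfg: SimConfig | None = None,
                 seed: int | None = None) -> tuple[Track, GroundTruth, RadiationSeries]:
    """Simulate one 1-Hz tracking day: rest — trips — rest.

    Identical configuration and seed give identical output.  Ground truth
    records, per trip, the departure/arrival boundary fixes (last inside /
    first back inside the colony radius on the noise-free path), the
    foraging-bout range and the commute modes; and per thermal its index
    range, exact ascent and climb rate.
    """
    cfg = cfg or SimConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    radiation = _day_radiation(cfg)
    day = pd.Timestamp(cfg.date)

    if cfg.trip_start_hours is not None:
        schedule = list(cfg.trip_start_hours)
    else:
        lo = cfg.sunrise_hour + 1.5
        hi = cfg.sunset_hour - 3.5
        schedule = list(np.linspace(lo, hi, cfg.n_trips)) if cfg.n_trips > 1 else [
            0.5 * (lo + hi)]
    schedule = sorted(schedule)

    start_time = day + pd.Timedelta(hours=schedule[0]) - pd.Timedelta(seconds=cfg.rest_pad_s)
    if cfg.full_day_rest:
        start_time = min(start_time,
                         day + pd.Timedelta(hours=cfg.sunrise_hour) - pd.Timedelta(minutes=5))

    def t_of_index(i: int) -> pd.Timestamp:
        return start_time + pd.Timedelta(seconds=int(i))

    builder = _PathBuilder(0.0, 0.0, 10.0)
    truth = GroundTruth()

    for k, hour in enumerate(schedule):
        target_s = (day + pd.Timedelta(hours=hour) - start_time).total_seconds()
        rest_needed = target_s - (builder.n - 1)
        _rest(builder, max(rest_needed, cfg.min_rest_s), rng)

        bearing = rng.uniform(0, 2 * np.pi)
        r_wh = radiation.at(t_of_index(builder.n - 1))
        p = thermal_availability(r_wh, cfg)
        out_mode = "soar" if rng.random() < p else "flap"
        in_mode = "soar" if rng.random() < p else "flap"
        dist = _draw_patch(cfg, out_mode, rng)
        patch = (dist * np.cos(bearing), dist * np.sin(bearing))

        trip_first = builder.n  # first commute sample
        _commute(builder, patch, out_mode, cfg, rng, radiation, t_of_index,
                 truth.thermals, "outward", k, final_agl=12.0)
        ev = builder.add(*_bout(builder.state, patch, cfg.patch_radius_m,
                                cfg.bout_duration_s, cfg, rng))
        _commute(builder, (0.0, 0.0), in_mode, cfg, rng, radiation, t_of_index,
                 truth.thermals, "inward", k, final_agl=10.0)
        trip_last = builder.n - 1
        truth.trips.append(TruthTrip(
            start=trip_first, end=trip_last,           # refined below
            event_start=ev[0], event_end=ev[1],
            outward_mode=out_mode, inward_mode=in_mode,
            patch_distance_m=dist))

    _rest(builder, cfg.rest_pad_s, rng)
    if cfg.full_day_rest:
        sunset_s = (day + pd.Timedelta(hours=cfg.sunset_hour) - start_time).total_seconds()
        _rest(builder, sunset_s + 300 - (builder.n - 1), rng)

    x, y, agl = builder.arrays()
    dist_col = np.hypot(x, y)

    # refine trip boundaries to the radius crossings on the noise-free path
    for tt in truth.trips:
        s, e = tt.start, tt.end
        seg = dist_col[s:e + 1]
        outside = np.flatnonzero(seg > cfg.colony_radius_m)
        first_out = s + int(outside[0])
        last_out = s + int(outside[-1])
        tt.start = first_out - 1
        tt.end = last_out + 1
        tt.t_start = t_of_index(tt.start)
        tt.t_end = t_of_index(tt.end)
    for th in truth.thermals:
        th.t_start = t_of_index(th.start)
        th.t_end = t_of_index(th.end)

    track = _emit_track(cfg, x, y, agl, start_time, rng)
    return track, truth, radiation


def simulate_commute(cfg: SimConfig | None = None, seed: int | None = None,
                     start_hour: float = 12.0, mode: str | None = None,
                     distance_m: float | None = None
                     ) -> tuple[Track, list[TruthThermal], RadiationSeries, str]:
    """Simulate a single outward commuting flight (colony → patch).

    ``mode`` None draws flap/soar from the radiation-dependent
    availability.  Returns the 1-Hz track (noise applied), the true
    thermal list, the radiation series and the realised mode.
    """
    cfg = cfg or SimConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    radiation = _day_radiation(cfg)
    day = pd.Timestamp(cfg.date)
    start_time = day + pd.Timedelta(hours=start_hour)

    r_wh = radiation.at(start_time)
    if mode is None:
        mode = "soar" if rng.random() < thermal_availability(r_wh, cfg) else "flap"
    if distance_m is None:
        distance_m = _draw_patch(cfg, mode, rng)
    bearing = rng.uniform(0, 2 * np.pi)
    patch = (distance_m * np.cos(bearing), distance_m * np.sin(bearing))

    builder = _PathBuilder(0.0, 0.0, cfg.flap_agl_m)
    thermals: list[TruthThermal] = []

    def t_of_index(i: int) -> pd.Timestamp:
        return start_time + pd.Timedelta(seconds=int(i))

    _commute(builder, patch, mode, cfg, rng, radiation, t_of_index,
             thermals, "standalone", -1, final_agl=12.0)
    x, y, agl = builder.arrays()
    for th in thermals:
        th.t_start = t_of_index(th.start)
        th.t_end = t_of_index(th.end)
    track = _emit_track(cfg, x, y, agl, start_time, rng)
    return track, thermals, radiation, mode


def downsample(track: Track, interval_s: float) -> Track:
    """Thin a track to a coarser sampling interval.

    ``interval_s`` must be an integer multiple of the source interval;
    fixes at times congruent to the track start modulo the interval are
    kept.  ``downsample(track, source_interval)`` is the identity.
    """
    src = track.sampling_interval
    ratio = interval_s / src
    if abs(ratio - round(ratio)) > 1e-9 or interval_s < src:
        raise ValueError(
            f"interval {interval_s}s is not a multiple of the source {src}s")
    t = track.fixes["timestamp"]
    offset = (t - t.iloc[0]).dt.total_seconds()
    keep = np.isclose(np.mod(offset, interval_s), 0.0)
    out = track.replace_fixes(track.fixes[keep])
    out.sampling_interval = float(interval_s)
    return out


def make_dem(lon_min: float, lon_max: float, lat_min: float, lat_max: float,
             cellsize_deg: float = 0.001, base_elevation_m: float = 60.0,
             hills: list[tuple[float, float, float, float]] | None = None) -> DemGrid:
    """Build a DEM: a flat base plane plus optional Gaussian hills.

    ``hills`` entries are (lon, lat, amplitude_m, sigma_deg).
    """
    ncols = max(2, int(np.ceil((lon_max - lon_min) / cellsize_deg)))
    nrows = max(2, int(np.ceil((lat_max - lat_min) / cellsize_deg)))
    lon_c = lon_min + (np.arange(ncols) + 0.5) * cellsize_deg
    lat_c = lat_min + (np.arange(nrows) + 0.5) * cellsize_deg
    grid = np.full((nrows, ncols), float(base_elevation_m))
    for (hl, hb, amp, sig) in hills or []:
        dlon = (lon_c[None, :] - hl) ** 2
        dlat = (lat_c[:, None] - hb) ** 2
        grid += amp * np.exp(-(dlon + dlat) / (2 * sig ** 2))
    grid = grid[::-1, :]  # row 0 = north
    return DemGrid(xllcorner=lon_min, yllcorner=lat_min,
                   cellsize=cellsize_deg, elevation=grid)


def dem_for_track(track: Track, cfg: SimConfig | None = None,
                  margin_deg: float = 0.02, **kwargs) -> DemGrid:
    """A flat DEM comfortably covering a track's bounding box."""
    base = (cfg.base_elevation_m if cfg is not None
            else kwargs.pop("base_elevation_m", 60.0))
    lon = track.fixes["lon"]
    lat = track.fixes["lat"]
    return make_dem(lon.min() - margin_deg, lon.max() + margin_deg,
                    lat.min() - margin_deg, lat.max() + margin_deg,
                    base_elevation_m=base, **kwargs)


def write_simulation(outdir, track: Track, truth: GroundTruth,
                     radiation: RadiationSeries, cfg: SimConfig) -> None:
    """Persist a simulated day as the pipeline's input files."""
    from .tracking import write_track
    from .trips import Colony, write_colonies
    from .weather import write_radiation

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_track(track, outdir / "track.csv")
    (outdir / "truth.json").write_text(truth.to_json())
    write_radiation(radiation, outdir / "radiation.csv")
    from .dem import write_esri_ascii
    write_esri_ascii(dem_for_track(track, cfg), outdir / "dem.asc")
    write_colonies([Colony(cfg.colony_id, cfg.colony_lon, cfg.colony_lat,
                           cfg.colony_radius_m)], outdir / "colony.csv")
    (outdir / "sim_config.json").write_text(json.dumps(cfg.as_dict(), indent=1))
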