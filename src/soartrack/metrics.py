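"""Commute- and trip-level flight variables, radiation joins and aggregates.

Per commuting flight: cross-country speed (beeline displacement over
duration by default; path-based optional), "maximum" flight altitude
taken as the third quartile of AGL (robust to single-fix GPS altitude
outliers), duration, path length, and the thermal-use ratios.  Per trip:
maximum distance from the colony and duration.  Each record is annotated
with solar radiation at its start time rounded to the nearest half-hour.
Variables are pooled per colony per 6-h UTC interval for joining with
coarse uplift estimates, and per-day foraging time is summed over
complete tracking days (sunrise-to-sunset coverage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import solar
from .geometry import local_xy
from .thermals import ThermalEvent, segment_path_length_km
from .tracking import Track
from .trips import Colony, ForagingTrip, colony_distances
from .weather import MissingWeatherError, RadiationSeries, interval_6h_start


def q3_altitude(agl: np.ndarray) -> float:
    """Third quartile of AGL (linear-interpolation / type-7 quantile)."""
    return float(np.quantile(np.asarray(agl, dtype=float), 0.75))


def commute_metrics(track: Track, commute_range: tuple[int, int],
                    commute_type: str, trip_id: str,
                    events: list[ThermalEvent] | None = None,
                    radiation: RadiationSeries | None = None,
                    path_speed: bool = False) -> dict:
    """Flight variables of one commuting flight (inclusive fix range)."""
    s, e = commute_range
    if e - s < 1:
        raise ValueError(f"commute {trip_id}/{commute_type}: fewer than 2 fixes")
    df = track.fixes.iloc[s:e + 1]
    t0, t1 = df["timestamp"].iloc[0], df["timestamp"].iloc[-1]
    duration_min = (t1 - t0).total_seconds() / 60.0

    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    x, y = local_xy(lon, lat, float(lon[0]), float(lat[0]))
    beeline_km = float(np.hypot(x[-1], y[-1]) / 1000.0)
    path_km = segment_path_length_km(df)
    basis_km = path_km if path_speed else beeline_km
    speed_kmh = basis_km / (duration_min / 60.0) if duration_min > 0 else 0.0

    rec = {
        "trip_id": trip_id,
        "commute": commute_type,
        "t_start": t0,
        "t_end": t1,
        "duration_min": duration_min,
        "max_altitude_q3_m": q3_altitude(df["agl"].to_numpy()),
        "cross_country_speed_kmh": speed_kmh,
        "path_length_km": path_km,
        "n_thermals": np.nan,
        "thermals_per_km": np.nan,
        "ascent_per_km_m": np.nan,
        "radiation_at_start": np.nan,
    }
    if events is not None:
        rec["n_thermals"] = len(events)
        if path_km > 0:
            rec["thermals_per_km"] = len(events) / path_km
            rec["ascent_per_km_m"] = sum(ev.total_ascent_m for ev in events) / path_km
    if radiation is not None:
        rec["radiation_at_start"] = radiation.at(t0)
    return rec


def trip_metrics(track: Track, trip: ForagingTrip, colony: Colony,
                 radiation: RadiationSeries | None = None,
                 n_thermals: int = 0) -> dict:
    """Trip-level variables: maximum colony distance, duration, radiation.

    Radiation is taken at the outward-commute start; when no outward
    commute was recorded the time of the first trip fix is used.
    """
    df = track.fixes.iloc[trip.start:trip.end + 1]
    dist = colony_distances(track.replace_fixes(df), colony)
    max_km = float(dist.max() / 1000.0)
    t0 = df["timestamp"].iloc[0]
    t1 = df["timestamp"].iloc[-1]
    rec = {
        "trip_id": trip.trip_id,
        "individual_id": trip.individual_id,
        "colony_id": trip.colony_id,
        "t_start": t0,
        "t_end": t1,
        "max_distance_km": max_km,
        "duration_min": (t1 - t0).total_seconds() / 60.0,
        "n_thermals": n_thermals,
        "has_thermals": n_thermals > 0,
        "radiation_at_start": np.nan,
    }
    if radiation is not None:
        rec["radiation_at_start"] = radiation.at(t0)
    if max_km * 1000.0 <= colony.radius_m:
        raise ValueError(
            f"trip {trip.trip_id} never leaves the colony radius — not a trip")
    return rec


def thermal_frequency_by_radiation(commutes: pd.DataFrame,
                                   bin_width: float = 200.0) -> pd.DataFrame:
    """Fraction of commuting flights with ≥1 thermal per radiation bin.

    Bins are half-open [0, w), [w, 2w), ...; empty bins are omitted.
    Only commutes with a thermal count (1-Hz) are considered.
    """
    df = commutes.dropna(subset=["n_thermals", "radiation_at_start"]).copy()
    if df.empty:
        return pd.DataFrame(columns=["bin_low", "bin_high", "n_commutes",
                                     "fraction_with_thermals"])
    df["bin_low"] = (df["radiation_at_start"] // bin_width) * bin_width
    rows = []
    for low, g in df.groupby("bin_low"):
        rows.append({
            "bin_low": float(low),
            "bin_high": float(low) + bin_width,
            "n_commutes": len(g),
            "fraction_with_thermals": float((g["n_thermals"] >= 1).mean()),
        })
    return pd.DataFrame(rows).sort_values("bin_low").reset_index(drop=True)


#: variables averaged on the log scale when log aggregation is on
LOG_VARIABLES = ("max_distance_km", "duration_min")


def _mean(series: pd.Series, log: bool) -> float:
    vals = series.dropna().astype(float)
    if vals.empty:
        return np.nan
    if log:
        vals = vals[vals > 0]
        if vals.empty:
            return np.nan
        return float(np.exp(np.log(vals).mean()))
    return float(vals.mean())


def aggregate_6h(commutes: pd.DataFrame | None = None,
                 trips: pd.DataFrame | None = None,
                 events: pd.DataFrame | None = None,
                 uplift: pd.DataFrame | None = None,
                 colony_id: str = "",
                 log_transform: bool = True) -> pd.DataFrame:
    """Pool flight variables per (colony, 6-h UTC interval).

    All individuals and flights at a colony falling in the same half-open
    interval (00/06/12/18 UTC) are averaged.  Trip distance and duration
    are averaged on the natural-log scale by default (their distributions
    are right-skewed), giving geometric-style means; set
    ``log_transform=False`` for arithmetic means.  Uplift records are
    joined by (colony, interval); intervals with no flights are omitted.
    """
    frames: dict[pd.Timestamp, dict] = {}

    def bucket(ts) -> dict:
        key = interval_6h_start(ts)
        return frames.setdefault(key, {"interval_start": key, "n_flights": 0})

    if commutes is not None and len(commutes):
        g = commutes.copy()
        g["interval_start"] = g["t_start"].map(interval_6h_start)
        for key, grp in g.groupby("interval_start"):
            b = frames.setdefault(key, {"interval_start": key, "n_flights": 0})
            b["mean_max_altitude_q3_m"] = _mean(grp["max_altitude_q3_m"], False)
            b["mean_cross_country_speed_kmh"] = _mean(grp["cross_country_speed_kmh"], False)
            b["mean_thermals_per_km"] = _mean(grp["thermals_per_km"], False)
            b["mean_ascent_per_km_m"] = _mean(grp["ascent_per_km_m"], False)
            b["n_flights"] += len(grp)
    if trips is not None and len(trips):
        g = trips.copy()
        g["interval_start"] = g["t_start"].map(interval_6h_start)
        for key, grp in g.groupby("interval_start"):
            b = frames.setdefault(key, {"interval_start": key, "n_flights": 0})
            b["mean_max_distance_km"] = _mean(grp["max_distance_km"], log_transform)
            b["mean_duration_min"] = _mean(grp["duration_min"], log_transform)
            b["n_flights"] += len(grp)
    if events is not None and len(events):
        g = events.copy()
        g["interval_start"] = g["t_start"].map(interval_6h_start)
        for key, grp in g.groupby("interval_start"):
            b = frames.setdefault(key, {"interval_start": key, "n_flights": 0})
            b["mean_total_ascent_m"] = _mean(grp["total_ascent_m"], False)
            b["mean_climb_speed_ms"] = _mean(grp["mean_climb_ms"], False)

    out = pd.DataFrame(sorted(frames.values(), key=lambda d: d["interval_start"]))
    if out.empty:
        return out
    out.insert(0, "colony_id", colony_id)
    out = out[out["n_flights"] >= 1].reset_index(drop=True)

    if uplift is not None and len(uplift):
        u = uplift[uplift["colony_id"].astype(str) == str(colony_id)]
        out = out.merge(
            u.drop(columns=["colony_id"]), on="interval_start", how="left")
    else:
        for col in ("thermal_uplift_ms", "orographic_srtm_ms", "orographic_aster_ms"):
            out[col] = np.nan
    return out


def daily_foraging_time(trips: pd.DataFrame, track: Track, colony: Colony,
                        gap_factor: float = 6.0) -> tuple[pd.DataFrame, dict]:
    """Foraging hours per (individual, date) and a complete-day summary.

    Foraging time is the summed duration of finalized trips (commutes plus
    foraging event).  A day is complete when fix coverage spans sunrise to
    sunset with no internal gap exceeding ``gap_factor`` x the sampling
    interval; the distribution summary (median, quartiles, range) uses
    complete days only.
    """
    t = track.fixes["timestamp"]
    per_day = []
    for date, g in t.groupby(t.dt.normalize()):
        rise, sett = solar.sunrise_sunset(date, colony.lon, colony.lat)
        day_fixes = g
        covered = (day_fixes.iloc[0] <= rise) and (day_fixes.iloc[-1] >= sett)
        within = day_fixes[(day_fixes >= rise) & (day_fixes <= sett)]
        max_gap = within.diff().dt.total_seconds().max() if len(within) > 1 else np.inf
        complete = bool(covered and max_gap <= gap_factor * track.sampling_interval)
        if len(trips):
            day_trips = trips[trips["t_start"].dt.normalize() == date]
            hours = day_trips["duration_min"].sum() / 60.0
        else:
            hours = 0.0
        per_day.append({
            "individual_id": track.individual_id,
            "date": date,
            "foraging_h": float(hours),
            "complete_day": complete,
        })
    table = pd.DataFrame(per_day)
    complete_h = table.loc[table["complete_day"], "foraging_h"]
    if len(complete_h):
        summary = {
            "n_complete_days": int(len(complete_h)),
            "median_h": float(complete_h.median()),
            "q1_h": float(complete_h.quantile(0.25)),
            "q3_h": float(complete_h.quantile(0.75)),
            "min_h": float(complete_h.min()),
            "max_h": float(complete_h.max()),
        }
    else:
        summary = {"n_complete_days": 0, "median_h": np.nan, "q1_h": np.nan,
                   "q3_h": np.nan, "min_h": np.nan, "max_h": np.nan}
    return table, summary
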