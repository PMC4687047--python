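"""Thermal-soaring event detection from circling geometry in 1-Hz tracks.

A thermal soaring event is a flight segment with a circular path lasting
more than 5 s, positive vertical speed, and a net altitude gain of at
least 10 m.  "Circular" is operationalised as sustained same-sign turning
at or above a minimum turn rate accumulating at least a minimum total
turn: a small raptor circling in a thermal (radius ~15–40 m at 7–10 m/s)
turns at roughly 12–35°/s, while heading noise on straight flight with
metre-scale GPS error stays well below that after smoothing.  Only the
climbing phase of each circling bout is kept (the gliding tail may hide
flapping), and total ascent is the endpoint height difference, which is
robust to altitude noise.

Detection requires 1-Hz data; coarser tracks cannot resolve circling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import circular_moving_average_deg, heading_deg, wrap_angle_deg
from .tracking import Track


class UnsupportedFrequencyError(ValueError):
    """Thermal detection needs ~1-Hz sampling."""


@dataclass
class DetectorParams:
    """Thermal-detector thresholds.

    ``min_duration_s`` (5 s) and ``min_ascent_m`` (10 m) define the event;
    the circling thresholds are artifact defaults (echoed into output
    metadata): turn rate ≥ 10°/s with consistent sign, cumulative turn
    ≥ 270°, sign flips shorter than 2 s tolerated, same-sign bouts closer
    than 5 s merged, headings smoothed over ±2 s.
    """

    min_turn_rate_deg_s: float = 10.0
    min_cumulative_turn_deg: float = 270.0
    flip_tolerance_s: float = 2.0
    merge_gap_s: float = 5.0
    smoothing_half_window_s: float = 2.0
    min_duration_s: float = 5.0
    min_ascent_m: float = 10.0
    climb_trim_window_s: float = 3.0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class ThermalEvent:
    """Climbing-phase circling segment, indices inclusive into the segment."""

    start: int
    end: int
    duration_s: float
    total_ascent_m: float
    mean_climb_ms: float
    circling_direction: str          # "clockwise" | "counterclockwise" | "mixed"
    cumulative_turn_deg: float

    def __post_init__(self) -> None:
        if not (self.duration_s > 0 and self.total_ascent_m > 0
                and self.mean_climb_ms > 0):
            raise ValueError("thermal event must climb over positive duration")


def _check_one_hz(seconds: np.ndarray) -> None:
    if seconds.size < 3:
        raise UnsupportedFrequencyError("need at least 3 fixes")
    med = float(np.median(np.diff(seconds)))
    if med > 2.0:
        raise UnsupportedFrequencyError(
            f"thermal detection needs 1-Hz data (median gap {med:.1f} s)")


def signed_turn_series(segment: pd.DataFrame,
                       params: DetectorParams | None = None) -> np.ndarray:
    """Per-step signed turning rate (deg/s, + clockwise) of a 1-Hz segment.

    Entry ``i`` is the heading change from step ``i`` to step ``i+1``;
    the array has ``len(segment) - 2`` entries.  Headings are smoothed by
    a circular moving average before differencing.
    """
    params = params or DetectorParams()
    t = (segment["timestamp"] - segment["timestamp"].iloc[0]).dt.total_seconds().to_numpy()
    _check_one_hz(t)
    lon = segment["lon"].to_numpy()
    lat = segment["lat"].to_numpy()
    from .geometry import local_xy
    x, y = local_xy(lon, lat, float(lon[0]), float(lat[0]))
    head = heading_deg(np.diff(x), np.diff(y))
    hw = int(round(params.smoothing_half_window_s))
    head = circular_moving_average_deg(head, hw)
    dturn = wrap_angle_deg(np.diff(head))
    dt = np.diff(t)[1:]
    return dturn / dt


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive index runs where mask is True."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size - 1)
    return list(zip(starts, ends))


def detect_circling(turn_rate: np.ndarray, seconds: np.ndarray,
                    params: DetectorParams | None = None) -> list[tuple[int, int]]:
    """Candidate circling ranges from a signed turn-rate series.

    Returns inclusive (start, end) *turn-series* index ranges.  Maximal
    runs of same-sign turning at ≥ the rate threshold are found, with
    sub-threshold or opposite-sign interruptions shorter than the flip
    tolerance absorbed; same-sign runs separated by ≤ the merge gap are
    merged; candidates below the cumulative-turn floor are discarded.
    """
    params = params or DetectorParams()
    out: list[tuple[int, int]] = []
    step = float(np.median(np.diff(seconds))) if seconds.size > 1 else 1.0
    flip_n = max(1, int(round(params.flip_tolerance_s / step)))
    merge_n = max(1, int(round(params.merge_gap_s / step)))

    for sign in (+1, -1):
        qual = sign * turn_rate >= params.min_turn_rate_deg_s
        runs = _runs_of(qual)
        if not runs:
            continue
        # absorb short interruptions, then merge across small gaps;
        # an interruption dominated by opposite-sign fast turning is kept
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            gap = s - pe - 1
            opposite = (-sign * turn_rate[pe + 1:s]
                        >= params.min_turn_rate_deg_s).sum()
            if (gap <= flip_n or gap <= merge_n) and opposite <= flip_n:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        for s, e in merged:
            cum = float(np.abs(turn_rate[s:e + 1].sum() * step))
            if cum >= params.min_cumulative_turn_deg:
                out.append((s, e))
    return sorted(out)


def _trim_to_climb(agl: np.ndarray, s: int, e: int, win: int) -> tuple[int, int]:
    """Trim leading/trailing stretches whose short-window net climb is
    negative, keeping the climbing phase of a circling bout."""
    while e - s >= win and agl[min(s + win, e)] - agl[s] < 0:
        s += 1
    while e - s >= win and agl[e] - agl[max(e - win, s)] < 0:
        e -= 1
    return s, e


def detect_thermal_events(track: Track | pd.DataFrame,
                          index_range: tuple[int, int] | None = None,
                          params: DetectorParams | None = None) -> list[ThermalEvent]:
    """Detect thermal soaring events in a 1-Hz commuting segment.

    ``index_range`` restricts detection to an inclusive fix range of the
    track (e.g. one commute); event indices are absolute into the track.
    Requires AGL to be attached.
    """
    params = params or DetectorParams()
    df = track.fixes if isinstance(track, Track) else track
    off = 0
    if index_range is not None:
        off = index_range[0]
        df = df.iloc[index_range[0]:index_range[1] + 1]
    if len(df) < 8:
        return []
    t = (df["timestamp"] - df["timestamp"].iloc[0]).dt.total_seconds().to_numpy()
    turn = signed_turn_series(df, params)
    agl = df["agl"].to_numpy(dtype=float)
    if np.isnan(agl).any():
        raise ValueError("thermal detection requires AGL on every fix")
    win = max(1, int(round(params.climb_trim_window_s)))

    events: list[ThermalEvent] = []
    for ts_, te_ in detect_circling(turn, t[2:], params):
        # turn index i summarises fixes [i, i+2]; candidate fix range:
        fs, fe = ts_, te_ + 2
        fs, fe = _trim_to_climb(agl, fs, fe, win)
        duration = t[fe] - t[fs]
        ascent = agl[fe] - agl[fs]
        if duration <= params.min_duration_s or ascent < params.min_ascent_m:
            continue
        mean_climb = ascent / duration
        if mean_climb <= 0:
            continue
        # direction bookkeeping over the trimmed range
        tr = turn[max(fs - 0, 0):fe - 1]
        cw = float(tr[tr > 0].sum())
        ccw = float(-tr[tr < 0].sum())
        cum = cw + ccw
        if cum > 0 and min(cw, ccw) / cum > 0.2:
            direction = "mixed"
        else:
            direction = "clockwise" if cw >= ccw else "counterclockwise"
        events.append(ThermalEvent(
            start=off + fs, end=off + fe,
            duration_s=float(duration),
            total_ascent_m=float(ascent),
            mean_climb_ms=float(mean_climb),
            circling_direction=direction,
            cumulative_turn_deg=cum,
        ))
    # enforce time order and non-overlap (keep the longer of overlapping pair)
    events.sort(key=lambda ev: ev.start)
    cleaned: list[ThermalEvent] = []
    for ev in events:
        if cleaned and ev.start <= cleaned[-1].end:
            if ev.duration_s > cleaned[-1].duration_s:
                cleaned[-1] = ev
            continue
        cleaned.append(ev)
    return cleaned


def segment_path_length_km(df: pd.DataFrame) -> float:
    """Horizontal path length of a fix segment, km."""
    from .geometry import local_xy
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    x, y = local_xy(lon, lat, float(lon[0]), float(lat[0]))
    return float(np.hypot(np.diff(x), np.diff(y)).sum() / 1000.0)


def thermal_summary(events: list[ThermalEvent], segment: pd.DataFrame) -> dict:
    """Per-segment thermal-use variables.

    Returns the number of events, events per km of horizontal path,
    accumulated ascent per km, and the per-event ascent and climb-speed
    lists (the four thermal-use variables).
    """
    path_km = segment_path_length_km(segment)
    if path_km <= 0:
        raise ValueError("segment has zero horizontal path length")
    ascents = [ev.total_ascent_m for ev in events]
    climbs = [ev.mean_climb_ms for ev in events]
    return {
        "n_events": len(events),
        "events_per_km": len(events) / path_km,
        "ascent_per_km_m": float(np.sum(ascents)) / path_km,
        "ascents_m": ascents,
        "climb_speeds_ms": climbs,
        "path_length_km": path_km,
    }
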