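"""Foraging-trip segmentation for a central-place forager.

A foraging trip is a maximal excursion outside the colony presence radius
(default 300 m) that contains an identifiable foraging event — a stretch
of clumped locations at low height above ground with highly variable
instantaneous speed.  Each trip splits into an outward commuting flight
(colony → foraging event), the foraging event, and an inward commuting
flight (event → colony).  Excursions whose departure from or arrival at
the colony was not recorded are incomplete and discarded, as are
excursions spanning the night (roosting away from the colony).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import local_xy
from .tracking import Track

logger = logging.getLogger(__name__)


@dataclass
class Colony:
    """Central place: the breeding colony with its presence radius."""

    colony_id: str
    lon: float
    lat: float
    radius_m: float = 300.0

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValueError("colony radius must be positive")


def read_colonies(path) -> list[Colony]:
    df = pd.read_csv(path, comment="#")
    required = {"colony_id", "lon", "lat", "radius_m"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: colony file needs columns {sorted(required)}")
    return [Colony(str(r.colony_id), float(r.lon), float(r.lat), float(r.radius_m))
            for r in df.itertuples()]


def write_colonies(colonies: list[Colony], path) -> None:
    pd.DataFrame([{"colony_id": c.colony_id, "lon": c.lon, "lat": c.lat,
                   "radius_m": c.radius_m} for c in colonies]).to_csv(path, index=False)


@dataclass
class SegmentationParams:
    """Tunable thresholds for trip and foraging-event identification.

    The foraging-event thresholds (window length, clump radius, event
    altitude ceiling, speed variability) operationalise "clumped locations
    at low altitude with highly variable instantaneous speed"; they are
    artifact defaults calibrated on the simulator and must be echoed into
    output metadata.
    """

    colony_radius_m: float = 300.0
    min_displacement_m: float = 300.0   # excursions must reach beyond this
    window_s: float = 60.0              # foraging-event scoring window
    clump_radius_m: float = 150.0       # max radius of gyration in a window
    max_event_agl_m: float = 30.0       # max median AGL in a window
    min_speed_cv: float = 0.6           # min coefficient of variation of speed
    max_gap_s: float | None = None      # colony-presence gap tolerance (None: 2x interval)
    exclude_night: bool = True
    night_start_hour: int = 21          # UTC; trips spanning [21:00, 04:00) dropped
    night_end_hour: int = 4

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class ForagingTrip:
    """A finalized trip: inclusive fix-index ranges into the source track."""

    trip_id: str
    individual_id: str
    colony_id: str
    start: int                      # last fix inside radius before departure
    end: int                        # first fix back inside radius
    event_start: int
    event_end: int
    sampling_interval: float

    @property
    def outward(self) -> tuple[int, int]:
        return (self.start, self.event_start)

    @property
    def inward(self) -> tuple[int, int]:
        return (self.event_end, self.end)

    def __post_init__(self) -> None:
        ok = (self.start < self.event_start <= self.event_end < self.end)
        if not ok:
            raise ValueError(
                f"trip {self.trip_id}: invalid ranges start={self.start} "
                f"event=({self.event_start},{self.event_end}) end={self.end}")


def colony_distances(track: Track, colony: Colony) -> np.ndarray:
    """Planar distance (m) of every fix to the colony."""
    x, y = local_xy(track.fixes["lon"].to_numpy(), track.fixes["lat"].to_numpy(),
                    colony.lon, colony.lat)
    return np.hypot(x, y)


def _merge_excursions(runs: list[tuple[int, int]], seconds: np.ndarray,
                      max_gap_s: float) -> list[tuple[int, int]]:
    """Merge outside-runs separated by colony re-entries shorter than the
    gap tolerance (a single missed or wandering fix must not split a trip)."""
    if not runs:
        return runs
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        inside_span = seconds[s] - seconds[pe]
        if inside_span <= max_gap_s:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def segment_trips(track: Track, colony: Colony,
                  params: SegmentationParams | None = None) -> list[tuple[int, int]]:
    """Find candidate trips as inclusive index ranges [departure, arrival].

    ``departure`` is the last fix inside the presence radius before the
    excursion; ``arrival`` the first fix back inside.  Excursions that do
    not reach beyond ``min_displacement_m``, that miss a recorded
    departure or arrival, or that span the night window are discarded.
    """
    params = params or SegmentationParams()
    if len(track) < 3:
        return []
    dist = colony_distances(track, colony)
    if dist.min() > 200_000:
        logger.warning("colony %s is >200 km from every fix — check configuration",
                       colony.colony_id)
    seconds = track.seconds()
    outside = dist > params.colony_radius_m

    # maximal runs of outside fixes
    arr = outside.astype(int)
    boundaries = np.flatnonzero(np.diff(arr) != 0) + 1
    segs = np.split(np.arange(len(arr)), boundaries)
    runs = [(int(seg[0]), int(seg[-1]))
            for seg in segs if len(seg) and outside[seg[0]]]

    max_gap = params.max_gap_s if params.max_gap_s is not None \
        else 2.0 * track.sampling_interval
    runs = _merge_excursions(runs, seconds, max_gap)

    candidates: list[tuple[int, int]] = []
    threshold = max(params.colony_radius_m, params.min_displacement_m)
    for s, e in runs:
        if s == 0 or e == len(track) - 1:
            continue  # incomplete: no recorded departure or arrival
        if dist[s:e + 1].max() <= threshold:
            continue
        dep, arr_ = s - 1, e + 1
        if params.exclude_night and _spans_night(
                track.fixes["timestamp"].iloc[dep],
                track.fixes["timestamp"].iloc[arr_],
                params.night_start_hour, params.night_end_hour):
            continue
        candidates.append((dep, arr_))
    return candidates


def _spans_night(t0: pd.Timestamp, t1: pd.Timestamp,
                 night_start: int, night_end: int) -> bool:
    """True when [t0, t1] intersects the nightly [night_start, night_end) window."""
    t = pd.Timestamp(t0).floor("h")
    while t <= t1:
        h = t.hour
        in_night = (h >= night_start) or (h < night_end)
        if in_night and t + pd.Timedelta(hours=1) > t0:
            return True
        t += pd.Timedelta(hours=1)
    return False


def _false_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive index runs where mask is False."""
    arr = (~np.asarray(mask, bool)).astype(int)
    boundaries = np.flatnonzero(np.diff(arr) != 0) + 1
    segs = np.split(np.arange(len(arr)), boundaries)
    return [(int(s[0]), int(s[-1])) for s in segs if len(s) and arr[s[0]]]


def detect_foraging_event(track: Track, trip_range: tuple[int, int],
                          params: SegmentationParams | None = None,
                          colony: Colony | None = None) -> tuple[int, int] | None:
    """Locate the foraging event inside a candidate trip.

    Trailing windows of ``window_s`` are scored on three criteria:
    (a) radius of gyration ≤ clump radius, (b) median AGL ≤ the event
    altitude ceiling, (c) coefficient of variation of instantaneous speed
    ≥ the variability threshold.  The event is the longest run of
    consecutive qualifying windows.  Criterion (c) is waived when a
    window holds fewer than 4 fixes (coarse sampling), where a speed CV
    is meaningless.
    """
    params = params or SegmentationParams()
    s, e = trip_range
    df = track.fixes.iloc[s:e + 1]
    n = len(df)
    dt = track.sampling_interval
    w = max(3, int(round(params.window_s / dt)))
    if n < w:
        return None

    origin = (float(df["lon"].iloc[0]), float(df["lat"].iloc[0]))
    x, y = local_xy(df["lon"].to_numpy(), df["lat"].to_numpy(), *origin)
    agl = df["agl"].to_numpy(dtype=float)
    speed = df["speed"].to_numpy(dtype=float)
    if np.isnan(speed).all():
        # fall back to derived ground speed
        d = np.hypot(np.diff(x), np.diff(y))
        ts = (df["timestamp"] - df["timestamp"].iloc[0]).dt.total_seconds().to_numpy()
        speed = np.concatenate([[np.nan], d / np.diff(ts)])

    xs = pd.Series(x)
    ys = pd.Series(y)
    # radius of gyration: sqrt(var(x) + var(y)) over the window
    mx = xs.rolling(w).mean()
    my = ys.rolling(w).mean()
    mx2 = (xs ** 2).rolling(w).mean()
    my2 = (ys ** 2).rolling(w).mean()
    rog = np.sqrt(np.maximum(mx2 - mx ** 2 + my2 - my ** 2, 0.0)).to_numpy()

    med_agl = pd.Series(agl).rolling(w).median().to_numpy()
    sp = pd.Series(speed)
    sp_mean = sp.rolling(w, min_periods=max(2, w - 1)).mean()
    sp_std = sp.rolling(w, min_periods=max(2, w - 1)).std()
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = (sp_std / sp_mean).to_numpy()

    qual = (rog <= params.clump_radius_m) & (med_agl <= params.max_event_agl_m)
    if w >= 4:
        # NaN comparisons are False, so incomplete windows never qualify
        qual &= cv >= params.min_speed_cv

    # close non-qualifying gaps shorter than one window (the window is the
    # smoothing scale; isolated failures must not split a long bout)
    gaps = _false_runs(qual)
    for gs, ge in gaps:
        if gs > 0 and ge < len(qual) - 1 and (ge - gs + 1) < w:
            qual[gs:ge + 1] = True

    # longest run of consecutive qualifying trailing-window end indices
    best_len, best_end, cur = 0, -1, 0
    for i, q in enumerate(qual):
        cur = cur + 1 if q else 0
        if cur > best_len:
            best_len, best_end = cur, i
    if best_len == 0:
        return None
    ev_end = best_end
    ev_start = best_end - best_len + 1 - (w - 1)
    ev_start = max(ev_start, 0)
    return (s + ev_start, s + ev_end)


def finalize_trips(track: Track, colony: Colony,
                   candidates: list[tuple[int, int]],
                   events: list[tuple[int, int] | None]) -> list[ForagingTrip]:
    """Keep candidates with an interior foraging event and name the commutes.

    Candidates without an event, or whose event touches a trip boundary
    (leaving an empty commute), are dropped.
    """
    trips: list[ForagingTrip] = []
    for k, ((s, e), ev) in enumerate(zip(candidates, events)):
        if ev is None:
            continue
        es, ee = ev
        if es <= s or ee >= e:
            logger.info("trip candidate %d: event touches boundary, dropped", k)
            continue
        trips.append(ForagingTrip(
            trip_id=f"{track.individual_id}-{k:03d}",
            individual_id=track.individual_id,
            colony_id=colony.colony_id,
            start=s, end=e, event_start=es, event_end=ee,
            sampling_interval=track.sampling_interval))
    return trips


def extract_trips(track: Track, colony: Colony,
                  params: SegmentationParams | None = None) -> list[ForagingTrip]:
    """Segment, detect foraging events and finalize in one call."""
    params = params or SegmentationParams()
    candidates = segment_trips(track, colony, params)
    events = [detect_foraging_event(track, c, params) for c in candidates]
    return finalize_trips(track, colony, candidates, events)


def trips_table(trips: list[ForagingTrip], track: Track) -> pd.DataFrame:
    """Flat CSV-ready table of finalized trips."""
    t = track.fixes["timestamp"]
    rows = []
    for tr in trips:
        rows.append({
            "trip_id": tr.trip_id,
            "individual_id": tr.individual_id,
            "colony_id": tr.colony_id,
            "t_start": t.iloc[tr.start],
            "t_end": t.iloc[tr.end],
            "t_event_start": t.iloc[tr.event_start],
            "t_event_end": t.iloc[tr.event_end],
            "sampling_interval_s": tr.sampling_interval,
        })
    return pd.DataFrame(rows)
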