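"""Track container, Movebank-style CSV I/O, QC filtering and step kinematics.

A :class:`Track` wraps a time-ordered table of GPS fixes for one
individual.  Fix quality is screened with the standard biologging rules
(minimum satellite count, maximum dilution of precision) and height above
ground (AGL) is derived by subtracting DEM terrain elevation from the GPS
altitude; fixes that end up below ground are treated as bad altitude
readings and dropped.

Timestamps are timezone-naive UTC throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dem import DemGrid
from .geometry import heading_deg, local_xy

logger = logging.getLogger(__name__)

#: Supported sampling intervals, seconds.
SAMPLING_INTERVALS = (1, 60, 180, 300, 600)

#: Fix-table columns, in canonical order.  ``speed`` is the device-reported
#: instantaneous ground speed (m/s); ``agl`` is absent until attach_agl.
FIX_COLUMNS = ["timestamp", "lon", "lat", "gps_altitude",
               "speed", "n_satellites", "dop", "agl"]

#: Default (Movebank-like) CSV column mapping.
MOVEBANK_DIALECT = {
    "individual_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "gps_altitude": "height-above-msl",
    "speed": "ground-speed",
    "n_satellites": "gps-satellite-count",
    "dop": "gps-dop",
}

REQUIRED_FIELDS = ("timestamp", "lon", "lat", "gps_altitude")


class TrackFormatError(ValueError):
    """The input file cannot be interpreted as a fix table."""


@dataclass
class QcReport:
    """Book-keeping of fixes removed by each screening rule."""

    n_in: int = 0
    n_out: int = 0
    few_satellites: int = 0
    high_dop: int = 0
    negative_altitude: int = 0

    @property
    def n_removed(self) -> int:
        return self.few_satellites + self.high_dop + self.negative_altitude

    def __post_init__(self) -> None:
        if self.n_in - self.n_out != self.n_removed:
            raise ValueError("QC counts inconsistent: removed + retained != input")


@dataclass
class Track:
    """Time-ordered GPS fixes of one individual."""

    individual_id: str
    fixes: pd.DataFrame
    sampling_interval: float
    colony_id: str = ""

    def __post_init__(self) -> None:
        df = self.fixes
        for col in FIX_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        self.fixes = df.loc[:, FIX_COLUMNS].reset_index(drop=True)
        ts = self.fixes["timestamp"]
        if len(ts) > 1 and (not ts.is_monotonic_increasing or ts.duplicated().any()):
            raise ValueError("fix timestamps must be strictly increasing")
        lon, lat = self.fixes["lon"], self.fixes["lat"]
        if ((lon < -180) | (lon > 180)).any() or ((lat < -90) | (lat > 90)).any():
            raise ValueError("lon/lat outside valid ranges")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def has_agl(self) -> bool:
        return len(self) > 0 and self.fixes["agl"].notna().all()

    def times(self) -> pd.Series:
        return self.fixes["timestamp"]

    def seconds(self) -> np.ndarray:
        """Elapsed seconds since the first fix."""
        t = self.fixes["timestamp"]
        return (t - t.iloc[0]).dt.total_seconds().to_numpy()

    def replace_fixes(self, fixes: pd.DataFrame) -> "Track":
        return Track(self.individual_id, fixes.reset_index(drop=True).copy(),
                     self.sampling_interval, self.colony_id)


def infer_sampling_interval(timestamps: pd.Series) -> float:
    """Mode of inter-fix gaps snapped to the supported interval set.

    Gaps within ±20 % of a supported interval snap to it; others are
    ignored.  Falls back to the raw median gap if nothing snaps.
    """
    gaps = pd.Series(timestamps).diff().dt.total_seconds().dropna().to_numpy()
    if gaps.size == 0:
        return 1.0
    grid = np.array(SAMPLING_INTERVALS, dtype=float)
    nearest = grid[np.argmin(np.abs(gaps[:, None] - grid[None, :]), axis=1)]
    ok = np.abs(gaps - nearest) <= 0.2 * nearest
    if not ok.any():
        return float(np.median(gaps))
    snapped = nearest[ok]
    values, counts = np.unique(snapped, return_counts=True)
    return float(values[np.argmax(counts)])


def read_track(path, dialect: dict | None = None,
               individual_id: str | None = None) -> Track:
    """Read a fix table CSV into a :class:`Track`.

    ``dialect`` maps canonical field names to the file's column names
    (default: Movebank conventions).  Rows are sorted by time and
    duplicate timestamps collapsed to the first occurrence.
    """
    path = Path(path)
    dialect = {**MOVEBANK_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, comment="#")
    missing = [f for f in REQUIRED_FIELDS if dialect.get(f) not in df.columns]
    if missing:
        raise TrackFormatError(
            f"{path}: missing required columns for fields {missing} "
            f"(dialect: { {f: dialect.get(f) for f in missing} })")
    out = pd.DataFrame()
    out["timestamp"] = pd.to_datetime(df[dialect["timestamp"]])
    for fld in ("lon", "lat", "gps_altitude"):
        out[fld] = pd.to_numeric(df[dialect[fld]], errors="coerce")
    for fld in ("speed", "n_satellites", "dop"):
        col = dialect.get(fld)
        out[fld] = pd.to_numeric(df[col], errors="coerce") if col in df.columns else np.nan
    out = out.dropna(subset=["timestamp", "lon", "lat", "gps_altitude"])
    if out.empty:
        raise TrackFormatError(f"{path}: no parseable fixes")
    out = out.sort_values("timestamp", kind="mergesort")
    dup = out["timestamp"].duplicated()
    if dup.any():
        logger.warning("%s: dropped %d duplicate-timestamp fixes", path, int(dup.sum()))
        out = out[~dup]
    if individual_id is None:
        col = dialect.get("individual_id")
        individual_id = str(df[col].iloc[0]) if col in df.columns else path.stem
    interval = infer_sampling_interval(out["timestamp"])
    return Track(individual_id, out.reset_index(drop=True), interval)


def write_track(track: Track, path, dialect: dict | None = None) -> None:
    """Write a track as CSV using the given (default Movebank) dialect."""
    dialect = {**MOVEBANK_DIALECT, **(dialect or {})}
    df = pd.DataFrame()
    df[dialect["individual_id"]] = np.repeat(track.individual_id, len(track))
    for fld in ("timestamp", "lon", "lat", "gps_altitude", "speed",
                "n_satellites", "dop"):
        df[dialect[fld]] = track.fixes[fld].values
    df.to_csv(Path(path), index=False)


def qc_filter(track: Track, min_satellites: float = 4,
              max_dop: float = 3.0) -> tuple[Track, QcReport]:
    """Screen fixes on satellite count and dilution of precision.

    Removes fixes seen by fewer than ``min_satellites`` satellites or with
    DOP strictly greater than ``max_dop``.  Fixes lacking either quality
    field pass: absence means the receiver dialect omitted the field, not
    that the fix is poor.
    """
    df = track.fixes
    nsat = df["n_satellites"]
    dop = df["dop"]
    bad_sat = nsat.notna() & (nsat < min_satellites)
    bad_dop = dop.notna() & (dop > max_dop) & ~bad_sat  # count each fix once
    keep = ~(bad_sat | bad_dop)
    report = QcReport(n_in=len(df), n_out=int(keep.sum()),
                      few_satellites=int(bad_sat.sum()),
                      high_dop=int(bad_dop.sum()))
    return track.replace_fixes(df[keep]), report


def attach_agl(track: Track, dem: DemGrid,
               drop_negative: bool = True,
               negative_rule: str = "agl") -> tuple[Track, QcReport]:
    """Derive height above ground and screen negative-altitude fixes.

    AGL = GPS altitude − terrain elevation at the nearest DEM cell.  With
    ``drop_negative``, fixes whose altitude is negative are removed and
    counted under ``negative_altitude``; ``negative_rule`` selects whether
    "negative" means AGL < 0 (default — the derived height discussed
    alongside the rule) or raw GPS altitude < 0 ("raw").
    """
    if negative_rule not in ("agl", "raw"):
        raise ValueError("negative_rule must be 'agl' or 'raw'")
    df = track.fixes.copy()
    if len(df) == 0:
        return track.replace_fixes(df), QcReport()
    elev = np.atleast_1d(dem.elevation_at(df["lon"].to_numpy(), df["lat"].to_numpy()))
    df["agl"] = df["gps_altitude"].to_numpy() - elev
    if drop_negative:
        bad = (df["agl"] < 0) if negative_rule == "agl" else (df["gps_altitude"] < 0)
    else:
        bad = pd.Series(False, index=df.index)
    report = QcReport(n_in=len(df), n_out=int((~bad).sum()),
                      negative_altitude=int(bad.sum()))
    return track.replace_fixes(df[~bad]), report


def step_kinematics(track: Track, origin: tuple[float, float] | None = None) -> pd.DataFrame:
    """Per-step distance, heading, ground speed and climb rate.

    Row ``i`` describes the step from fix ``i`` to fix ``i+1`` (the last
    row is NaN).  Climb rate requires AGL; it is NaN otherwise.
    """
    df = track.fixes
    if len(df) < 2:
        raise ValueError("step kinematics need at least 2 fixes")
    if origin is None:
        origin = (float(df["lon"].iloc[0]), float(df["lat"].iloc[0]))
    x, y = local_xy(df["lon"].to_numpy(), df["lat"].to_numpy(), *origin)
    dt = np.diff((df["timestamp"] - df["timestamp"].iloc[0]).dt.total_seconds().to_numpy())
    if (dt <= 0).any():
        raise ValueError("non-increasing timestamps in track")
    dx, dy = np.diff(x), np.diff(y)
    dist = np.hypot(dx, dy)
    head = heading_deg(dx, dy)
    speed = dist / dt
    agl = df["agl"].to_numpy(dtype=float)
    climb = np.diff(agl) / dt
    pad = [np.nan]
    return pd.DataFrame({
        "distance_m": np.concatenate([dist, pad]),
        "heading_deg": np.concatenate([head, pad]),
        "ground_speed_ms": np.concatenate([speed, pad]),
        "climb_ms": np.concatenate([climb, pad]),
        "dt_s": np.concatenate([dt, pad]),
    }, index=df.index)
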