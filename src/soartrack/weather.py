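"""Weather inputs: half-hourly solar radiation and 6-hourly uplift tables.

Solar radiation (Wh/m², from a pyranometer logging every 30 minutes) is
the proxy for thermal formation; flight variables are annotated with the
radiation value at the observation time rounded to the nearest half-hour.
Thermal and orographic uplift (m/s) come from weather-model reanalysis at
6-hour resolution, one record per colony per interval, and are joined to
6-hour aggregates of the flight variables.

All timestamps are timezone-naive UTC.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class MissingWeatherError(KeyError):
    """A required weather record is absent from the series."""


HALF_HOUR = pd.Timedelta(minutes=30)


def round_to_half_hour(t) -> pd.Timestamp:
    """Round a timestamp to the nearest :00/:30 boundary; exact midpoints
    (:15, :45) round up."""
    t = pd.Timestamp(t)
    floored = t.floor("30min")
    if (t - floored) >= pd.Timedelta(minutes=15):
        return floored + HALF_HOUR
    return floored


class RadiationSeries:
    """Half-hourly solar radiation series, Wh/m²."""

    def __init__(self, values: pd.Series):
        s = pd.Series(values).astype(float)
        s.index = pd.DatetimeIndex(s.index)
        if len(s) and not ((s.index.minute.isin([0, 30])) & (s.index.second == 0)).all():
            raise ValueError("radiation timestamps must lie on :00/:30 boundaries")
        if (s < 0).any():
            raise ValueError("radiation values must be non-negative")
        self.series = s.sort_index()

    def __len__(self) -> int:
        return len(self.series)

    def at(self, t) -> float:
        """Radiation at ``t`` rounded to the nearest half-hour."""
        if not len(self.series):
            raise MissingWeatherError("radiation series is empty")
        key = round_to_half_hour(t)
        try:
            return float(self.series.loc[key])
        except KeyError:
            raise MissingWeatherError(
                f"no radiation record at {key} (query {pd.Timestamp(t)})"
            ) from None


def radiation_at(series: RadiationSeries, t) -> float:
    """Functional alias for :meth:`RadiationSeries.at`."""
    return series.at(t)


def read_radiation(path) -> RadiationSeries:
    df = pd.read_csv(path, comment="#")
    if not {"timestamp", "radiation_wh_m2"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns timestamp, radiation_wh_m2")
    return RadiationSeries(
        pd.Series(df["radiation_wh_m2"].values,
                  index=pd.to_datetime(df["timestamp"]))
    )


def write_radiation(series: RadiationSeries, path) -> None:
    pd.DataFrame({
        "timestamp": series.series.index,
        "radiation_wh_m2": series.series.values,
    }).to_csv(Path(path), index=False)


UPLIFT_COLUMNS = ["interval_start", "colony_id", "thermal_uplift_ms",
                  "orographic_srtm_ms", "orographic_aster_ms"]


def read_uplift(path) -> pd.DataFrame:
    """Read a 6-hourly uplift table; one row per (colony, interval)."""
    df = pd.read_csv(path, comment="#")
    missing = set(UPLIFT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: uplift table missing columns {sorted(missing)}")
    df = df.copy()
    df["interval_start"] = pd.to_datetime(df["interval_start"])
    if not (df["interval_start"].dt.hour.isin([0, 6, 12, 18])
            & (df["interval_start"].dt.minute == 0)).all():
        raise ValueError("uplift interval_start must lie on 6-h boundaries (00/06/12/18 UTC)")
    if df.duplicated(["interval_start", "colony_id"]).any():
        raise ValueError("uplift table has duplicate (colony, interval) records")
    return df


def write_uplift(df: pd.DataFrame, path) -> None:
    df.loc[:, UPLIFT_COLUMNS].to_csv(Path(path), index=False)


def interval_6h_start(t) -> pd.Timestamp:
    """Start of the half-open 6-h UTC interval (00/06/12/18) containing ``t``."""
    t = pd.Timestamp(t)
    return t.normalize() + pd.Timedelta(hours=6 * (t.hour // 6))


def make_radiation(day, peak: float, sunrise, sunset) -> RadiationSeries:
    """Idealised clear-sky half-hourly radiation curve for one day.

    Zero before sunrise and after sunset, a half-sine in between peaking at
    solar noon: R(t) = peak * sin(pi * (t - sunrise) / (sunset - sunrise)).
    """
    day = pd.Timestamp(day).normalize()
    sunrise = pd.Timestamp(sunrise)
    sunset = pd.Timestamp(sunset)
    if sunrise >= sunset:
        raise ValueError("sunrise must precede sunset")
    times = pd.date_range(day, day + pd.Timedelta(hours=23, minutes=30), freq="30min")
    frac = (times - sunrise) / (sunset - sunrise)
    values = peak * np.sin(np.pi * np.clip(frac, 0.0, 1.0))
    values = np.where((frac < 0) | (frac > 1), 0.0, np.maximum(values, 0.0))
    return RadiationSeries(pd.Series(values, index=times))
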