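"""End-to-end orchestration: read → QC → AGL → trips → thermals → metrics →
aggregates → energetics, with persisted stage outputs and a run manifest.

Every stage writes its table before the next runs, so any stage can be
re-run in isolation; the manifest records thresholds, seeds and row
counts, making a run a pure function of its inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dem import read_esri_ascii
from .energetics import (EnergeticsConfig, Morphology, ModelConstants, daily_energy,
                         flapping_powers, power_curve, prey_balance, resting_power,
                         soaring_power, trip_energy)
from .metrics import (aggregate_6h, commute_metrics, daily_foraging_time,
                      thermal_frequency_by_radiation, trip_metrics)
from .thermals import DetectorParams, detect_thermal_events
from .tracking import attach_agl, qc_filter, read_track
from .trips import (Colony, SegmentationParams, extract_trips, read_colonies,
                    trips_table)
from .weather import read_radiation, read_uplift

logger = logging.getLogger(__name__)


def _write_with_metadata(df: pd.DataFrame, path: Path, metadata: dict) -> None:
    """CSV with a JSON metadata header line (comment-prefixed)."""
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(metadata, default=str) + "\n")
        df.to_csv(fh, index=False)


def run_pipeline(track_path, dem_path, radiation_path, colony_path,
                 out_dir, uplift_path=None,
                 seg_params: SegmentationParams | None = None,
                 det_params: DetectorParams | None = None,
                 energetics_config: EnergeticsConfig | None = None,
                 morphology: Morphology | None = None,
                 path_speed: bool = False,
                 seed: int = 0) -> dict:
    """Run all stages on one track; returns the manifest dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg_params = seg_params or SegmentationParams()
    det_params = det_params or DetectorParams()
    e_cfg = energetics_config or EnergeticsConfig()
    morph = morphology or Morphology()
    manifest: dict = {
        "soartrack_version": __version__,
        "seed": seed,
        "inputs": {"track": str(track_path), "dem": str(dem_path),
                   "radiation": str(radiation_path), "colony": str(colony_path),
                   "uplift": str(uplift_path) if uplift_path else None},
        "thresholds": {"segmentation": seg_params.as_dict(),
                       "thermal_detector": det_params.as_dict()},
        "stages": {},
    }

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    # --- read -------------------------------------------------------------
    st = stage("read")
    track = read_track(track_path)
    colony = read_colonies(colony_path)[0]
    radiation = read_radiation(radiation_path)
    dem = read_esri_ascii(dem_path)
    uplift = read_uplift(uplift_path) if uplift_path else None
    st["n_fixes"] = len(track)
    st["sampling_interval_s"] = track.sampling_interval

    # --- QC and AGL -------------------------------------------------------
    st = stage("qc")
    track, qc_rep = qc_filter(track)
    track, agl_rep = attach_agl(track, dem)
    st["removed_few_satellites"] = qc_rep.few_satellites
    st["removed_high_dop"] = qc_rep.high_dop
    st["removed_negative_altitude"] = agl_rep.negative_altitude
    st["n_fixes_retained"] = len(track)

    # --- segmentation -----------------------------------------------------
    st = stage("segment")
    trips = extract_trips(track, colony, seg_params)
    ttable = trips_table(trips, track)
    _write_with_metadata(ttable, out / "trips.csv",
                         {"thresholds": seg_params.as_dict()})
    st["n_trips"] = len(trips)

    # --- thermal detection (1-Hz only) ------------------------------------
    st = stage("thermals")
    one_hz = track.sampling_interval <= 2.0
    events_by_commute: dict[tuple[str, str], list] = {}
    event_rows = []
    if one_hz:
        for tr in trips:
            for label, rng_ in (("outward", tr.outward), ("inward", tr.inward)):
                evs = detect_thermal_events(track, rng_, det_params)
                events_by_commute[(tr.trip_id, label)] = evs
                for ev in evs:
                    event_rows.append({
                        "trip_id": tr.trip_id, "commute": label,
                        "t_start": track.fixes["timestamp"].iloc[ev.start],
                        "t_end": track.fixes["timestamp"].iloc[ev.end],
                        "duration_s": ev.duration_s,
                        "total_ascent_m": ev.total_ascent_m,
                        "mean_climb_ms": ev.mean_climb_ms,
                        "direction": ev.circling_direction,
                        "cumulative_turn_deg": ev.cumulative_turn_deg,
                    })
    events_df = pd.DataFrame(event_rows)
    _write_with_metadata(events_df, out / "thermal_events.csv",
                         {"thresholds": det_params.as_dict(), "one_hz": one_hz})
    st["n_events"] = len(event_rows)

    # --- metrics ----------------------------------------------------------
    st = stage("metrics")
    commute_rows, trip_rows = [], []
    for tr in trips:
        n_th = 0
        for label, rng_ in (("outward", tr.outward), ("inward", tr.inward)):
            evs = events_by_commute.get((tr.trip_id, label)) if one_hz else None
            commute_rows.append(commute_metrics(
                track, rng_, label, tr.trip_id, events=evs,
                radiation=radiation, path_speed=path_speed))
            n_th += len(evs) if evs else 0
        trip_rows.append(trip_metrics(track, tr, colony, radiation, n_thermals=n_th))
    commutes_df = pd.DataFrame(commute_rows)
    trips_df = pd.DataFrame(trip_rows)
    meta = {"path_speed": path_speed,
            "thresholds": {**seg_params.as_dict(), **det_params.as_dict()}}
    _write_with_metadata(commutes_df, out / "commute_metrics.csv", meta)
    _write_with_metadata(trips_df, out / "trip_metrics.csv", meta)
    st["n_commutes"] = len(commutes_df)
    st["n_trips"] = len(trips_df)

    # --- aggregates -------------------------------------------------------
    st = stage("aggregate")
    bins = thermal_frequency_by_radiation(commutes_df) if len(commutes_df) else \
        pd.DataFrame()
    _write_with_metadata(bins, out / "fig3_bins.csv", {"bin_width_wh_m2": 200})
    agg = aggregate_6h(commutes_df if len(commutes_df) else None,
                       trips_df if len(trips_df) else None,
                       events_df if len(events_df) else None,
                       uplift=uplift, colony_id=colony.colony_id)
    _write_with_metadata(agg, out / "aggregates_6h.csv", {"log_transform": True})
    daily, daily_summary = daily_foraging_time(trips_df, track, colony) \
        if len(trips_df) else (pd.DataFrame(), {})
    _write_with_metadata(daily, out / "daily_foraging.csv", daily_summary)
    st["n_intervals"] = len(agg)

    # --- energetics -------------------------------------------------------
    st = stage("energetics")
    t_forage = daily_summary.get("median_h")
    if t_forage is None or not np.isfinite(t_forage) or t_forage <= 0:
        t_forage = 7.48  # fall back to a typical breeding-season median
    mean_trip_min = float(trips_df["duration_min"].mean()) if len(trips_df) \
        else e_cfg.mean_trip_duration_min
    report = energetics_report(e_cfg, morph, t_forage_h=t_forage,
                               trip_duration_min=mean_trip_min)
    _write_with_metadata(report, out / "energy_budget.csv",
                         {"t_forage_h": t_forage,
                          "trip_duration_min": mean_trip_min})
    st["t_forage_h"] = t_forage

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def energetics_report(e_cfg: EnergeticsConfig | None = None,
                      morph: Morphology | None = None,
                      const: ModelConstants | None = None,
                      t_forage_h: float = 7.48,
                      trip_duration_min: float | None = None) -> pd.DataFrame:
    """Daily-energy-ledger table for the three strategies.

    Rows: soaring-gliding, flapping at Vmp, flapping at Vmr; columns:
    flight power, per-trip energy, DEE components and the prey count
    needed to balance two foraging trips.
    """
    e_cfg = e_cfg or EnergeticsConfig()
    morph = morph or Morphology()
    p_rest = resting_power(e_cfg.resting_vo2_ml_min, e_cfg.o2_energy_kj_per_l)
    curve = power_curve(morph, const, maintenance_power_w=p_rest)
    p_vmp, p_vmr = flapping_powers(curve)
    p_soar = soaring_power(p_rest, e_cfg.soaring_multiplier)
    dur = trip_duration_min if trip_duration_min is not None \
        else e_cfg.mean_trip_duration_min
    rows = []
    for name, p in (("soaring-gliding", p_soar),
                    ("flapping_vmp", p_vmp),
                    ("flapping_vmr", p_vmr)):
        budget = daily_energy(t_forage_h, p, p_rest)
        e_trip = trip_energy(p, dur)
        rows.append({
            "strategy": name,
            "flight_power_w": round(p, 2),
            "resting_power_w": round(p_rest, 2),
            "trip_energy_kj": round(e_trip, 2),
            "dee_forage_kj": round(budget.dee_forage_kj, 2),
            "dee_rest_kj": round(budget.dee_rest_kj, 2),
            "dee_total_kj": round(budget.dee_total_kj, 2),
            "prey_per_2_trips": prey_balance(e_trip, e_cfg.prey_energy_kj, 2),
        })
    df = pd.DataFrame(rows)
    df.attrs["vmp_kmh"] = curve.vmp_kmh
    df.attrs["vmr_kmh"] = curve.vmr_kmh
    return df


def _group_block(df: pd.DataFrame, cols: list[str]) -> list[str]:
    lines = []
    n = len(df)
    for c in cols:
        v = df[c].dropna().astype(float)
        if not len(v):
            continue
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        flag = " (n=1)" if len(v) == 1 else ""
        lines.append(f"  {c}: mean {v.mean():.2f} ± {sd:.2f}, "
                     f"min {v.min():.2f}, max {v.max():.2f}, n {len(v)}{flag}")
    if not lines:
        lines.append(f"  (empty group, n={n})")
    return lines


def build_report(out_dir) -> str:
    """Human-readable summary of pipeline outputs (grouped mean ± SD blocks).

    Sections mirror the study's summary tables: with/without-thermal
    commute comparison, thermal-use variables, all-frequency flight
    variables, and the daily energy ledger.  Empty groups are noted, not
    fatal.
    """
    out = Path(out_dir)

    def load(name):
        p = out / name
        if not p.exists():
            return pd.DataFrame()
        df = pd.read_csv(p, comment="#")
        for c in df.columns:
            if c.startswith("t_"):
                df[c] = pd.to_datetime(df[c])
        return df

    commutes = load("commute_metrics.csv")
    trips = load("trip_metrics.csv")
    events = load("thermal_events.csv")
    budget = load("energy_budget.csv")

    lines = ["# Flight summary report", ""]
    lines.append("## Commuting flights with vs without thermal soaring")
    if len(commutes) and commutes["n_thermals"].notna().any():
        with_th = commutes[commutes["n_thermals"] >= 1]
        without = commutes[commutes["n_thermals"] == 0]
        cols = ["max_altitude_q3_m", "duration_min", "cross_country_speed_kmh"]
        lines.append(f"with thermals (n={len(with_th)}):")
        lines += _group_block(with_th, cols)
        lines.append(f"without thermals (n={len(without)}):")
        lines += _group_block(without, cols)
        total = len(with_th) + len(without)
        lines.append(f"groups partition {total} of {len(commutes)} commutes")
    else:
        lines.append("  (no 1-Hz commutes — empty group)")

    lines += ["", "## Thermal-use variables (per commute / per event)"]
    if len(commutes):
        lines += _group_block(commutes, ["thermals_per_km", "ascent_per_km_m"])
    if len(events):
        lines += _group_block(events, ["total_ascent_m", "mean_climb_ms"])
    else:
        lines.append("  (no thermal events — empty group)")

    lines += ["", "## All-frequency flight variables"]
    if len(commutes):
        lines += _group_block(commutes, ["cross_country_speed_kmh",
                                         "max_altitude_q3_m"])
    if len(trips):
        lines += _group_block(trips, ["max_distance_km", "duration_min"])

    lines += ["", "## Daily energy expenditure ledger"]
    if len(budget):
        lines.append(budget.to_string(index=False))
    else:
        lines.append("  (no energetics output)")
    report = "\n".join(lines) + "\n"
    (out / "report.md").write_text(report)
    return report
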