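"""Shared fixtures: simulated days/commutes prepared through QC and AGL."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import soartrack as st

try:  # derandomise hypothesis when present
    from hypothesis import settings
    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def flat_dem():
    """One flat 60-m DEM generously covering every simulated flight."""
    cfg = st.SimConfig()
    return st.make_dem(cfg.colony_lon - 0.25, cfg.colony_lon + 0.25,
                       cfg.colony_lat - 0.25, cfg.colony_lat + 0.25,
                       cellsize_deg=0.002, base_elevation_m=cfg.base_elevation_m)


@pytest.fixture(scope="session")
def colony():
    cfg = st.SimConfig()
    return st.Colony(cfg.colony_id, cfg.colony_lon, cfg.colony_lat, cfg.colony_radius_m)


def prepare(track: st.Track, dem) -> st.Track:
    """QC-filter and attach AGL, as the pipeline would."""
    t, _ = st.qc_filter(track)
    t, _ = st.attach_agl(t, dem)
    return t


@pytest.fixture(scope="session")
def noisefree_day(flat_dem):
    """A noise-free simulated day plus its prepared track and truth."""
    cfg = st.SimConfig(seed=3, sigma_xy_m=0.0, sigma_z_m=0.0,
                       bad_fix_prob=0.0, speed_noise_ms=0.0)
    track, truth, radiation = st.simulate_day(cfg)
    return cfg, prepare(track, flat_dem), track, truth, radiation


@pytest.fixture(scope="session")
def noisy_day(flat_dem):
    """A default-noise simulated day plus its prepared track and truth."""
    cfg = st.SimConfig(seed=3)
    track, truth, radiation = st.simulate_day(cfg)
    return cfg, prepare(track, flat_dem), track, truth, radiation


def truth_to_filtered(raw_track: st.Track, filtered: st.Track,
                      start_idx: int, end_idx: int) -> tuple[int, int]:
    """Map a truth index range on the raw track to the filtered track."""
    ts = filtered.fixes["timestamp"]
    t0 = raw_track.fixes["timestamp"].iloc[start_idx]
    t1 = raw_track.fixes["timestamp"].iloc[end_idx]
    return int(ts.searchsorted(t0)), int(ts.searchsorted(t1, side="right")) - 1


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union


@pytest.fixture(scope="session")
def grouped(flat_dem):
    """Commute metrics over 10 simulated days, labelled with true modes."""
    rows = []
    for seed in range(10):
        cfg = st.SimConfig(seed=200 + seed, n_trips=3)
        raw, truth, radiation = st.simulate_day(cfg)
        track = prepare(raw, flat_dem)
        colony = st.Colony(cfg.colony_id, cfg.colony_lon, cfg.colony_lat)
        trips = st.extract_trips(track, colony)
        for tr, tt in zip(trips, truth.trips):
            for label, rng_, mode in (("outward", tr.outward, tt.outward_mode),
                                      ("inward", tr.inward, tt.inward_mode)):
                evs = st.detect_thermal_events(track, rng_)
                rec = st.commute_metrics(track, rng_, label, tr.trip_id,
                                         events=evs, radiation=radiation)
                rec["seed"] = seed
                rec["mode"] = mode
                rec["trip_distance_km"] = tt.patch_distance_m / 1000
                rows.append(rec)
    return pd.DataFrame(rows)


def match_events(true_ranges, detected_ranges, min_jaccard=0.5):
    """Greedy one-to-one matching; returns the number of matched pairs."""
    used: set[int] = set()
    pairs = []
    for a in true_ranges:
        best, best_j = None, 0.0
        for i, b in enumerate(detected_ranges):
            if i in used:
                continue
            j = interval_jaccard(a, b)
            if j > best_j:
                best, best_j = i, j
        if best is not None and best_j >= min_jaccard:
            used.add(best)
            pairs.append((a, best))
    return pairs
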