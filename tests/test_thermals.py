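"""Circling geometry, thermal-event detection and the brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

import soartrack as st
from soartrack.thermals import ThermalEvent

from conftest import match_events, prepare, truth_to_filtered


def circle_track(radius=20.0, speed=8.0, duration=60, climb=0.0, agl0=50.0,
                 direction=1):
    """A perfect 1-Hz circular (optionally climbing) flight as a Track."""
    t = np.arange(duration + 1, dtype=float)
    omega = speed / radius
    x = radius * np.cos(direction * omega * t)
    y = radius * np.sin(direction * omega * t)
    lon, lat = st.inverse_local_xy(x, y, -6.05, 37.35)
    fixes = pd.DataFrame({
        "timestamp": pd.Timestamp("2012-06-15 10:00:00") + pd.to_timedelta(t, unit="s"),
        "lon": lon, "lat": lat, "gps_altitude": 60.0 + agl0 + climb * t,
        "speed": speed, "n_satellites": 8.0, "dop": 1.0,
        "agl": agl0 + climb * t,
    })
    return st.Track("bird", fixes, 1.0)


def straight_track(speed=8.0, duration=60, climb=0.0, agl0=50.0, bearing=90.0):
    t = np.arange(duration + 1, dtype=float)
    x = speed * t * np.sin(np.radians(bearing))
    y = speed * t * np.cos(np.radians(bearing))
    lon, lat = st.inverse_local_xy(x, y, -6.05, 37.35)
    fixes = pd.DataFrame({
        "timestamp": pd.Timestamp("2012-06-15 10:00:00") + pd.to_timedelta(t, unit="s"),
        "lon": lon, "lat": lat, "gps_altitude": 60.0 + agl0 + climb * t,
        "speed": speed, "n_satellites": 8.0, "dop": 1.0,
        "agl": agl0 + climb * t,
    })
    return st.Track("bird", fixes, 1.0)


class TestTurnSeries:
    def test_straight_flight_turns_near_zero(self):
        turns = st.signed_turn_series(straight_track().fixes)
        assert np.abs(turns).max() < 0.5

    def test_circle_turn_rate_closed_form(self):
        # 360 * v / (2 pi r) deg/s for a perfect circle
        turns = st.signed_turn_series(circle_track(radius=20, speed=8).fixes)
        expected = 360 * 8 / (2 * np.pi * 20)
        inner = turns[3:-3]  # away from smoothing edges
        np.testing.assert_allclose(inner, -expected, rtol=0.02)

    def test_heading_wrap(self):
        assert st.wrap_angle_deg(10 - 350) == pytest.approx(20.0)

    def test_coarse_sampling_rejected(self):
        track = straight_track()
        coarse = track.replace_fixes(track.fixes.iloc[::10])
        with pytest.raises(st.UnsupportedFrequencyError):
            st.signed_turn_series(coarse.fixes)


class TestDetectCircling:
    seconds = np.arange(200, dtype=float)

    def test_sustained_circling_single_candidate(self):
        turn = np.zeros(120)
        turn[20:80] = 20.0
        cands = st.detect_circling(turn, self.seconds[:120])
        assert len(cands) == 1
        s, e = cands[0]
        assert abs(s - 20) <= 1 and abs(e - 79) <= 1
        assert abs(turn[s:e + 1].sum()) == pytest.approx(1200, rel=0.05)

    def test_short_circling_below_cumulative_floor(self):
        turn = np.zeros(60)
        turn[10:14] = 20.0  # 80 degrees total
        assert st.detect_circling(turn, self.seconds[:60]) == []

    def test_nearby_bouts_merged(self):
        turn = np.zeros(120)
        turn[10:40] = 20.0
        turn[43:73] = 20.0  # 3-s gap <= 5-s merge tolerance
        cands = st.detect_circling(turn, self.seconds[:120])
        assert len(cands) == 1
        assert cands[0][0] <= 10 and cands[0][1] >= 72

    def test_opposite_sign_bouts_not_merged(self):
        turn = np.zeros(200)
        turn[10:60] = 20.0
        turn[64:114] = -20.0
        cands = st.detect_circling(turn, self.seconds)
        assert len(cands) == 2


class TestDetectEvents:
    def test_climbing_helix_recovered_exactly(self):
        track = circle_track(duration=60, climb=1.2)
        events = st.detect_thermal_events(track)
        assert len(events) == 1
        ev = events[0]
        assert ev.total_ascent_m == pytest.approx(72.0, abs=6.0)
        assert ev.mean_climb_ms == pytest.approx(1.2, abs=0.1)
        assert ev.circling_direction == "counterclockwise"

    def test_small_gain_rejected(self):
        track = circle_track(duration=60, climb=5.0 / 60.0)  # 5 m over a minute
        assert st.detect_thermal_events(track) == []

    def test_straight_climb_is_not_a_thermal(self):
        track = straight_track(duration=60, climb=1.5)
        assert st.detect_thermal_events(track) == []

    def test_descending_circling_rejected(self):
        track = circle_track(duration=60, climb=-1.0, agl0=120.0)
        assert st.detect_thermal_events(track) == []


class TestThermalSummary:
    def _ev(self, ascent, dur=60.0):
        return ThermalEvent(0, 10, dur, ascent, ascent / dur, "clockwise", 1200.0)

    def test_rates_per_km(self):
        seg = straight_track(speed=10, duration=500).fixes  # 5 km beeline
        summary = st.thermal_summary([self._ev(100.0), self._ev(50.0)], seg)
        assert summary["events_per_km"] == pytest.approx(0.4, rel=0.01)
        assert summary["ascent_per_km_m"] == pytest.approx(30.0, rel=0.01)

    def test_no_events(self):
        seg = straight_track(speed=10, duration=500).fixes
        summary = st.thermal_summary([], seg)
        assert summary["events_per_km"] == 0 and summary["ascent_per_km_m"] == 0

    def test_extreme_ascent_representable(self):
        seg = straight_track(speed=10, duration=500).fixes
        summary = st.thermal_summary([self._ev(914.0, dur=600.0)], seg)
        assert summary["ascents_m"] == [914.0]

    def test_zero_path_length_rejected(self):
        seg = straight_track(speed=10, duration=3).fixes.copy()
        seg["lon"] = seg["lon"].iloc[0]
        seg["lat"] = seg["lat"].iloc[0]
        with pytest.raises(ValueError):
            st.thermal_summary([], seg)


# ---------------------------------------------------------------------------
# brute-force oracle: enumerate qualifying sub-ranges from first principles
# ---------------------------------------------------------------------------

def oracle_events(df: pd.DataFrame, params: st.DetectorParams) -> list[tuple[int, int]]:
    """All maximal index sub-ranges satisfying the event definition.

    Recomputes headings/turns with its own loops, then enumerates every
    sub-range of consistently fast same-sign turning and filters on
    cumulative turn, duration, ascent and mean climb, keeping ranges not
    contained in a longer qualifying one.
    """
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    x, y = st.local_xy(lon, lat, float(lon[0]), float(lat[0]))
    agl = df["agl"].to_numpy(float)
    head = np.degrees(np.arctan2(np.diff(x), np.diff(y)))
    hw = int(params.smoothing_half_window_s)
    # edge-padded circular moving average, written longhand
    padded = np.concatenate([[head[0]] * hw, head, [head[-1]] * hw])
    sm = np.empty_like(head)
    for i in range(len(head)):
        win = np.radians(padded[i:i + 2 * hw + 1])
        sm[i] = np.degrees(np.arctan2(np.sin(win).mean(), np.cos(win).mean()))
    turn = np.array([(d + 180) % 360 - 180 for d in np.diff(sm)])

    cum_turn = np.concatenate([[0.0], np.cumsum(turn)])
    win = int(params.climb_trim_window_s)
    merge_n = int(params.merge_gap_s)
    flip_n = int(params.flip_tolerance_s)
    qualifying = set()
    for sign in (1, -1):
        ok = sign * turn >= params.min_turn_rate_deg_s
        opp = (-sign * turn) >= params.min_turn_rate_deg_s
        for i in np.flatnonzero(ok):
            # extend forward from each qualifying start; interruptions are
            # tolerated while shorter than the merge gap and not dominated
            # by opposite-sign circling
            gap = gap_opp = 0
            j = int(i)
            while j < len(turn):
                if ok[j]:
                    gap = gap_opp = 0
                else:
                    gap += 1
                    gap_opp += int(opp[j])
                    if gap > merge_n or gap_opp > flip_n:
                        break
                    j += 1
                    continue
                # candidate range ends at a qualifying step
                if abs(cum_turn[j + 1] - cum_turn[i]) >= \
                        params.min_cumulative_turn_deg:
                    fs, fe = int(i), j + 2  # fix range covered by the turns
                    dur = fe - fs
                    ascent = agl[fe] - agl[fs]
                    # climbing phase only: no descending edge window
                    edges_climb = (agl[min(fs + win, fe)] - agl[fs] >= 0
                                   and agl[fe] - agl[max(fe - win, fs)] >= 0)
                    if dur > params.min_duration_s and edges_climb and \
                            ascent >= params.min_ascent_m and ascent / dur > 0:
                        qualifying.add((fs, fe))
                j += 1
    # drop ranges contained in another qualifying range: sort by (start asc,
    # end desc); a range is maximal iff its end exceeds every end seen so far
    maximal = []
    best_end = -1
    for fs, fe in sorted(qualifying, key=lambda r: (r[0], -r[1])):
        if fe > best_end:
            maximal.append((fs, fe))
            best_end = fe
    return sorted(maximal)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_noise_free_commutes_match_oracle(self, seed, flat_dem):
        cfg = st.SimConfig(seed=seed, sigma_xy_m=0.0, sigma_z_m=0.0,
                           bad_fix_prob=0.0, speed_noise_ms=0.0)
        track, truth, _, _ = st.simulate_commute(cfg, mode="soar")
        track = prepare(track, flat_dem)
        params = st.DetectorParams()
        detected = [(ev.start, ev.end) for ev in
                    st.detect_thermal_events(track, params=params)]
        expected = oracle_events(track.fixes, params)
        assert detected == expected
        assert len(detected) == len(truth)


@pytest.fixture(scope="module")
def batch(flat_dem):
    out = []
    for seed in range(40):
        cfg = st.SimConfig(seed=seed)
        raw, truth, _, _ = st.simulate_commute(cfg, mode="soar",
                                               start_hour=9 + (seed % 10) / 2)
        track = prepare(raw, flat_dem)
        mapped = [truth_to_filtered(raw, track, t.start, t.end)
                  for t in truth]
        out.append((track, truth, mapped))
    return out


class TestRecoveryAndInvariants:
    def test_recall_precision_and_ascent_error(self, batch):
        n_true = n_det = n_match = 0
        errors = []
        for track, truth, mapped in batch:
            events = st.detect_thermal_events(track)
            n_true += len(truth)
            n_det += len(events)
            pairs = match_events(mapped, [(ev.start, ev.end) for ev in events])
            n_match += len(pairs)
            by_range = {(ev.start, ev.end): ev for ev in events}
            for (a, i) in pairs:
                ev = st.detect_thermal_events(track)[i]
                true_asc = truth[mapped.index(a)].ascent_m
                errors.append(abs(ev.total_ascent_m - true_asc) / true_asc)
        assert n_match / n_true >= 0.9
        assert n_match / n_det >= 0.9
        assert np.mean(errors) <= 0.15

    def test_event_invariants(self, batch):
        for track, _, _ in batch:
            events = st.detect_thermal_events(track)
            for prev, ev in zip(events, events[1:]):
                assert prev.end < ev.start  # non-overlap, time ordered
            for ev in events:
                assert ev.duration_s > 5
                assert ev.total_ascent_m >= 10
                assert ev.mean_climb_ms > 0
                assert 0 <= ev.start < ev.end < len(track)

    def test_stronger_climbs_detected_stronger(self, flat_dem):
        # same seed, increasing thermal strength: detected mean climb speed
        # must not decrease
        means = []
        for base in (0.5, 1.0, 1.6):
            cfg = st.SimConfig(seed=11, soar_climb_base_ms=base,
                               soar_climb_rad_coeff=0.0)
            raw, _, _, _ = st.simulate_commute(cfg, mode="soar")
            track = prepare(raw, flat_dem)
            events = st.detect_thermal_events(track)
            means.append(np.mean([ev.mean_climb_ms for ev in events]))
        assert means[0] <= means[1] <= means[2]
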