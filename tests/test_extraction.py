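"""Trip extraction on hand-constructed toy logs and synthetic fleets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import accelwalk as aw
from accelwalk import io as awio, synthetic, trip_extraction as tx

from conftest import SUITE_SEED

T0 = pd.Timestamp("2011-05-02 08:00:00")


def _ev(veh, minutes, x, y, kind, road=None):
    return {"vehicle_id": veh, "timestamp": T0 + pd.Timedelta(minutes=minutes),
            "x_km": float(x), "y_km": float(y), "kind": kind,
            "road_id": road}


def _drive(veh, t0_min, x0, x1, n_fix, speed_offset_min=1.0):
    """A simple straight drive: start, n_fix fixes, stop."""
    rows = [_ev(veh, t0_min, x0, 0.0, "engine_start")]
    xs = np.linspace(x0, x1, n_fix + 2)
    ts = np.linspace(t0_min + speed_offset_min,
                     t0_min + speed_offset_min * (n_fix + 1), n_fix)
    for t, x in zip(ts, xs[1:-1]):
        rows.append(_ev(veh, t, x, 0.0, "fix"))
    rows.append(_ev(veh, t0_min + speed_offset_min * (n_fix + 1), x1, 0.0,
                    "engine_stop"))
    return rows


class TestSegmentation:
    def test_four_minute_gap_merges_into_one_trip(self):
        rows = _drive("a", 0.0, 0.0, 5.0, 4) + _drive("a", 9.0, 5.0, 9.0, 4)
        trips, stops = tx.segment_trips(pd.DataFrame(rows))
        assert len(trips) == 1
        assert len(stops) == 0
        # duration spans first start to final stop, including the gap
        assert trips.iloc[0]["duration_h"] == pytest.approx(14.0 / 60.0)
        assert trips.iloc[0]["path_length_km"] == pytest.approx(9.0)

    def test_six_minute_gap_splits_and_records_stop(self):
        rows = _drive("a", 0.0, 0.0, 5.0, 4) + _drive("a", 11.0, 5.0, 9.0, 4)
        trips, stops = tx.segment_trips(pd.DataFrame(rows))
        assert len(trips) == 2
        assert len(stops) == 1
        gap_h = (stops.iloc[0]["t_on"] - stops.iloc[0]["t_off"]) \
            / pd.Timedelta(hours=1)
        assert gap_h == pytest.approx(6.0 / 60.0)

    def test_micro_gap_reversal_toward_origin_starts_new_trip(self):
        # 20 s gap, then motion heading straight back to the previous
        # origin: two trips
        out = _drive("a", 0.0, 0.0, 6.0, 5)
        back = _drive("a", 6.0 + 20.0 / 60.0, 6.0, 0.0, 5)
        trips, _ = tx.segment_trips(pd.DataFrame(out + back))
        assert len(trips) == 2

    def test_micro_gap_continuing_forward_merges(self):
        out = _drive("a", 0.0, 0.0, 6.0, 5)
        onward = _drive("a", 6.0 + 20.0 / 60.0, 6.0, 12.0, 5)
        trips, _ = tx.segment_trips(pd.DataFrame(out + onward))
        assert len(trips) == 1

    def test_intermediate_gap_band_merges_unconditionally(self):
        # 2-min gap with reversal still merges: only sub-30-s gaps are
        # tested against the return-to-origin rule
        out = _drive("a", 0.0, 0.0, 6.0, 5)
        back = _drive("a", 8.0, 6.0, 0.0, 5)
        trips, _ = tx.segment_trips(pd.DataFrame(out + back))
        assert len(trips) == 1

    def test_engine_on_time_conserved(self):
        rows = (_drive("a", 0.0, 0.0, 5.0, 4)
                + _drive("a", 9.0, 5.0, 9.0, 4)
                + _drive("a", 60.0, 9.0, 15.0, 4))
        df = pd.DataFrame(rows)
        trips, stops = tx.segment_trips(df)
        on_time = trips["duration_h"].sum() - trips["merged_gap_h"].sum()
        starts = df[df["kind"] == "engine_start"]["timestamp"].to_numpy()
        stops_t = df[df["kind"] == "engine_stop"]["timestamp"].to_numpy()
        raw_on = (stops_t - starts).sum() / np.timedelta64(1, "h")
        assert on_time == pytest.approx(raw_on, abs=1e-12)

    def test_unsorted_events_error_names_vehicle(self):
        rows = _drive("veh7", 0.0, 0.0, 5.0, 4)
        rows[2], rows[3] = rows[3], rows[2]
        with pytest.raises(ValueError, match="veh7"):
            tx.segment_trips(pd.DataFrame(rows))


class TestSignalLossCorrection:
    def test_displaced_origin_snapped_and_path_extended(self):
        trip1 = _drive("a", 0.0, 0.0, 5.0, 4)
        # next trip starts 0.5 km away from the previous stop
        trip2 = _drive("a", 30.0, 5.5, 9.0, 4)
        df = pd.DataFrame(trip1 + trip2)
        corrected, n = tx.correct_signal_loss(df, snap_threshold_km=0.1)
        assert n == 1
        trips_raw, _ = tx.segment_trips(df)
        trips_fix, _ = tx.segment_trips(corrected)
        delta = (trips_fix.iloc[1]["path_length_km"]
                 - trips_raw.iloc[1]["path_length_km"])
        # origin moved from 5.5 to 5.0: first hop grows by the 0.5 km gap
        assert delta == pytest.approx(0.5)

    def test_coincident_origin_untouched(self):
        df = pd.DataFrame(_drive("a", 0.0, 0.0, 5.0, 4)
                          + _drive("a", 30.0, 5.0, 9.0, 4))
        corrected, n = tx.correct_signal_loss(df)
        assert n == 0
        pd.testing.assert_frame_equal(corrected, df)

    def test_count_matches_injected_artifacts(self):
        sc = synthetic.SyntheticScenario(n_vehicles=6, days=2,
                                         signal_loss_rate=0.4,
                                         seed=SUITE_SEED)
        events, truth = synthetic.generate_fleet_log(sc)
        _, n = tx.correct_signal_loss(events)
        assert n == (truth["artifacts"]["kind"] == "signal_loss").sum()


class TestTripFilter:
    def test_packaged_seven_trip_fixture_leaves_three(self):
        trips = awio.load_filter_fixture()
        assert len(trips) == 7
        kept = tx.filter_trips(trips)
        assert len(kept) == 3
        assert set(kept["vehicle_id"]) == {"C", "F", "G"}

    @pytest.mark.parametrize("path,dur_h,survives", [
        (0.9, 10 / 60, False),     # too short
        (1.5, 4 / 60, False),      # too quick
        (1.0, 10 / 60, False),     # boundary length, strict inequality
        (2.0, 5 / 60, False),      # boundary duration
        (1.01, 5.1 / 60, True),
    ])
    def test_strict_inequalities(self, path, dur_h, survives):
        trips = pd.DataFrame({"vehicle_id": ["x"], "duration_h": [dur_h],
                              "mean_speed_kmh": [path / dur_h],
                              "path_length_km": [path]})
        assert len(tx.filter_trips(trips)) == (1 if survives else 0)


class TestFreeFlowSpeed:
    def test_uniform_grid_percentile(self):
        samples = pd.DataFrame({"road_id": "r",
                                "speed_kmh": np.arange(1.0, 101.0)})
        out = tx.free_flow_speed(samples)
        assert out.iloc[0]["free_flow_kmh"] == pytest.approx(85.15)
        assert not out.iloc[0]["low_confidence"]

    def test_constant_samples(self):
        samples = pd.DataFrame({"road_id": "r", "speed_kmh": [60.0] * 25})
        assert tx.free_flow_speed(samples).iloc[0]["free_flow_kmh"] == 60.0

    def test_matches_sort_based_oracle_on_random_multisets(self):
        def oracle(values, q=0.85):
            s = np.sort(values)
            pos = q * (s.size - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, s.size - 1)
            return s[lo] + (pos - lo) * (s[hi] - s[lo])

        rng = np.random.default_rng(SUITE_SEED)
        for _ in range(1000):
            n = rng.integers(1, 60)
            vals = np.round(rng.uniform(1.0, 140.0, size=n),
                            rng.integers(0, 3))
            table = tx.free_flow_speed(
                pd.DataFrame({"road_id": "r", "speed_kmh": vals}),
                min_samples=1)
            assert table.iloc[0]["free_flow_kmh"] == pytest.approx(
                oracle(vals), abs=1e-9)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(vals=st.lists(st.floats(min_value=0.1, max_value=200.0,
                                   allow_nan=False),
                         min_size=1, max_size=40))
    def test_percentile_property_against_sorted_oracle(self, vals):
        s = np.sort(np.asarray(vals))
        pos = 0.85 * (s.size - 1)
        lo = int(np.floor(pos))
        oracle = s[lo] + (pos - lo) * (s[min(lo + 1, s.size - 1)] - s[lo])
        table = tx.free_flow_speed(
            pd.DataFrame({"road_id": "r", "speed_kmh": vals}),
            min_samples=1)
        assert table.iloc[0]["free_flow_kmh"] == pytest.approx(oracle,
                                                               abs=1e-9)

    def test_small_roads_flagged(self):
        samples = pd.DataFrame({"road_id": ["r"] * 5,
                                "speed_kmh": np.linspace(30, 50, 5)})
        assert bool(tx.free_flow_speed(samples).iloc[0]["low_confidence"])


class TestFreeFlowProfile:
    @pytest.fixture(scope="class")
    def fleet(self):
        sc = synthetic.SyntheticScenario(n_vehicles=40, days=1,
                                         noise_sd_km=0.0, seed=SUITE_SEED)
        events, truth = synthetic.generate_fleet_log(sc)
        trips, _ = tx.segment_trips(events)
        return events, trips

    def _ff_table(self, events):
        fixes = events[events["kind"] == "fix"]
        # synthetic road ids encode the layer; map each to its layer speed
        params = aw.REFERENCE_PARAMS
        roads = fixes["road_id"].dropna().unique()
        return pd.DataFrame({
            "road_id": roads,
            "free_flow_kmh": [params.v0 + int(r[1]) * params.dv
                              for r in roads],
            "n": 100, "low_confidence": False,
        })

    def test_peak_sits_mid_trip_and_curve_is_normalized(self, fleet):
        events, trips = fleet
        profile = tx.free_flow_profile(events, trips, self._ff_table(events),
                                       t_center_h=0.5, half_width_h=0.25)
        assert profile.n_trips >= 5
        assert profile.curve.max() == pytest.approx(1.0)
        peak = profile.rel_time[np.argmax(profile.curve)]
        assert 0.45 <= peak <= 0.55

    def test_symmetric_inputs_give_symmetric_curve(self):
        # trapezoidal speed profiles symmetric about t/2 by construction
        rows, trips = [], []
        ff = pd.DataFrame({"road_id": ["slow", "fast"],
                           "free_flow_kmh": [30.0, 90.0]})
        for i in range(5):
            veh = f"s{i}"
            t0 = T0 + pd.Timedelta(hours=i)
            rows.append({"vehicle_id": veh, "timestamp": t0, "x_km": 0.0,
                         "y_km": 0.0, "kind": "engine_start",
                         "road_id": None})
            for frac, road in [(0.1, "slow"), (0.3, "fast"), (0.5, "fast"),
                               (0.7, "fast"), (0.9, "slow")]:
                rows.append({"vehicle_id": veh,
                             "timestamp": t0 + pd.Timedelta(hours=frac),
                             "x_km": frac * 10, "y_km": 0.0, "kind": "fix",
                             "road_id": road})
            rows.append({"vehicle_id": veh,
                         "timestamp": t0 + pd.Timedelta(hours=1.0),
                         "x_km": 10.0, "y_km": 0.0, "kind": "engine_stop",
                         "road_id": None})
            trips.append({"vehicle_id": veh, "t_start": t0,
                          "duration_h": 1.0})
        profile = tx.free_flow_profile(pd.DataFrame(rows),
                                       pd.DataFrame(trips), ff,
                                       t_center_h=1.0, n_grid=41)
        np.testing.assert_allclose(profile.curve, profile.curve[::-1],
                                   atol=1e-6)


class TestResidence:
    def _stops(self, veh, hours_by_area):
        rows, t = [], T0
        for area, h in hours_by_area:
            rows.append({"vehicle_id": veh, "t_off": t,
                         "t_on": t + pd.Timedelta(hours=h),
                         "x_km": 0.0, "y_km": 0.0, "area_id": area})
            t += pd.Timedelta(hours=h + 0.5)
        return pd.DataFrame(rows)

    def test_majority_parking_time_wins(self):
        res = tx.assign_residence(self._stops("v", [("A", 10.0),
                                                    ("B", 2.0)]))
        assert res.iloc[0]["area_id"] == "A"

    def test_tie_broken_by_first_observed_with_warning(self):
        stops = self._stops("v", [("B", 4.0), ("A", 4.0)])
        with pytest.warns(RuntimeWarning, match="tie"):
            res = tx.assign_residence(stops)
        assert res.iloc[0]["area_id"] == "B"

    def test_planted_residences_recovered(self):
        sc = synthetic.SyntheticScenario(n_vehicles=8, days=3,
                                         seed=SUITE_SEED)
        events, truth = synthetic.generate_fleet_log(sc)
        _, stops = tx.segment_trips(events)
        res = tx.assign_residence(synthetic.label_areas(stops))
        rests = truth["rests"]
        rests["park_h"] = (rests["t_on"] - rests["t_off"]) \
            / pd.Timedelta(hours=1)
        merged = res.merge(truth["residences"], on="vehicle_id",
                           suffixes=("_est", "_true"))
        for _, row in merged.iterrows():
            veh_rests = rests[rests["vehicle_id"] == row["vehicle_id"]]
            share = (veh_rests.loc[veh_rests["area_id"]
                                   == row["area_id_true"], "park_h"].sum()
                     / veh_rests["park_h"].sum())
            if share > 0.5:
                assert row["area_id_est"] == row["area_id_true"]

    def test_unlabelled_stops_rejected(self):
        stops = self._stops("v", [("A", 1.0)]).drop(columns="area_id")
        with pytest.raises(ValueError, match="area_id"):
            tx.assign_residence(stops)
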