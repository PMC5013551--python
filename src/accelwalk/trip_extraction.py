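"""Trip extraction from raw GPS engine-event logs.

An event log is a DataFrame with one row per event and columns
``vehicle_id``, ``timestamp`` (datetime), ``x_km``, ``y_km``,
``kind`` (``engine_start`` | ``engine_stop`` | ``fix``) and optionally
``road_id`` and ``quality``.  Coordinates are planar kilometres (geographic
input is converted at the I/O boundary).

Segmentation rules:

* an engine-off gap of at least 5 minutes ends a trip (shorter engine-off
  intervals are treated as accidental switch-offs or parking-search pauses
  and merged into the surrounding trip);
* a gap under 30 seconds is merged unconditionally *unless* the post-gap
  motion heads back toward the origin of the previous segment, in which
  case a genuine new trip has begun;
* trip duration runs from the first engine start to the final stop of the
  merged sequence (merged gaps count as driving time); path length sums
  consecutive point-to-point distances.

Signal-loss correction snaps a trip origin that lies implausibly far from
the previous stopping point back onto that stop.  Free-flow speed is the
85th percentile of per-road speed samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import MIN_TRIP_DURATION_H, MIN_TRIP_LENGTH_KM

__all__ = [
    "segment_trips",
    "correct_signal_loss",
    "filter_trips",
    "free_flow_speed",
    "free_flow_profile",
    "assign_residence",
    "FreeFlowProfile",
]

STOP_THRESHOLD_S = 300.0
MICRO_STOP_S = 30.0
SNAP_THRESHOLD_KM = 0.1
BACK_BEARING_DEG = 30.0

EVENT_COLUMNS = ["vehicle_id", "timestamp", "x_km", "y_km", "kind"]


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def _validate_vehicle_events(veh: str, ev: pd.DataFrame) -> None:
    ts = ev["timestamp"].to_numpy()
    bad = np.flatnonzero(np.diff(ts) < np.timedelta64(0, "s"))
    if bad.size:
        raise ValueError(
            f"events for vehicle {veh!r} not sorted at "
            f"{ev['timestamp'].iloc[bad[0] + 1]}")
    kinds = ev["kind"].tolist()
    expect_start = True
    for i, k in enumerate(kinds):
        if k == "engine_start":
            if not expect_start:
                raise ValueError(
                    f"vehicle {veh!r}: engine_start without preceding stop "
                    f"at {ev['timestamp'].iloc[i]}")
            expect_start = False
        elif k == "engine_stop":
            if expect_start:
                raise ValueError(
                    f"vehicle {veh!r}: engine_stop without running engine "
                    f"at {ev['timestamp'].iloc[i]}")
            expect_start = True
        elif k == "fix":
            if expect_start:
                raise ValueError(
                    f"vehicle {veh!r}: fix while engine off at "
                    f"{ev['timestamp'].iloc[i]}")
        else:
            raise ValueError(f"vehicle {veh!r}: unknown event kind {k!r}")


def _raw_segments(ev: pd.DataFrame):
    """Split one vehicle's validated events into engine-on segments."""
    segments = []
    current = None
    for row in ev.itertuples(index=False):
        if row.kind == "engine_start":
            current = {"t_on": row.timestamp, "times": [row.timestamp],
                       "pos": [(row.x_km, row.y_km)]}
        elif row.kind == "fix":
            current["times"].append(row.timestamp)
            current["pos"].append((row.x_km, row.y_km))
        else:  # engine_stop
            current["times"].append(row.timestamp)
            current["pos"].append((row.x_km, row.y_km))
            current["t_off"] = row.timestamp
            segments.append(current)
            current = None
    if current is not None:
        raise ValueError("log ends with the engine still running")
    return segments


def _heads_back_to_origin(prev_origin, next_pos,
                          bearing_deg: float = BACK_BEARING_DEG) -> bool:
    """True when the post-gap motion points back toward the previous
    segment's origin: first displacement within ``bearing_deg`` of the
    direction to the origin, and origin distance decreasing over the first
    three points."""
    pts = np.asarray(next_pos[:4], dtype=float)
    if pts.shape[0] < 2:
        return False
    origin = np.asarray(prev_origin, dtype=float)
    move = pts[1] - pts[0]
    to_origin = origin - pts[0]
    nm, no = np.linalg.norm(move), np.linalg.norm(to_origin)
    if nm == 0.0 or no == 0.0:
        return False
    cosang = float(np.dot(move, to_origin) / (nm * no))
    if cosang < math.cos(math.radians(bearing_deg)):
        return False
    dists = np.linalg.norm(pts[: min(3, pts.shape[0])] - origin, axis=1)
    return bool(np.all(np.diff(dists) < 0))


def _finalize_trip(veh: str, segs: list, merged_gap_s: float) -> dict:
    pos = []
    for s in segs:
        pos.extend(s["pos"])
    pos = np.asarray(pos, dtype=float)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    t0, t1 = segs[0]["t_on"], segs[-1]["t_off"]
    duration_h = (t1 - t0) / pd.Timedelta(hours=1)
    path = float(steps.sum())
    return {
        "vehicle_id": veh,
        "t_start": t0,
        "duration_h": duration_h,
        "mean_speed_kmh": path / duration_h if duration_h > 0 else np.nan,
        "path_length_km": path,
        "straight_line_km": _dist(pos[-1], pos[0]),
        "n_segments": len(segs),
        "merged_gap_h": merged_gap_s / 3600.0,
    }


def segment_trips(events: pd.DataFrame,
                  stop_threshold_s: float = STOP_THRESHOLD_S,
                  micro_stop_s: float = MICRO_STOP_S):
    """Segment an event log into trips and stop intervals.

    Returns ``(trips, stops)`` DataFrames.  Engine-off gaps of at least
    ``stop_threshold_s`` end a trip and open a stop interval; shorter gaps
    merge the surrounding segments, except that a gap under
    ``micro_stop_s`` whose post-gap motion heads back toward the previous
    segment's origin starts a new trip.
    """
    trips, stops = [], []
    for veh, ev in events.groupby("vehicle_id", sort=True):
        _validate_vehicle_events(veh, ev)
        segments = _raw_segments(ev)
        if not segments:
            continue
        pending = [segments[0]]
        gap_s = 0.0
        for seg in segments[1:]:
            prev = pending[-1]
            gap = (seg["t_on"] - prev["t_off"]) / pd.Timedelta(seconds=1)
            if gap < 0:
                raise ValueError(
                    f"vehicle {veh!r}: overlapping segments at {seg['t_on']}")
            split = gap >= stop_threshold_s
            if not split and gap < micro_stop_s:
                split = _heads_back_to_origin(prev["pos"][0], seg["pos"])
            if split:
                trips.append(_finalize_trip(veh, pending, gap_s))
                stops.append({
                    "vehicle_id": veh,
                    "t_off": prev["t_off"], "t_on": seg["t_on"],
                    "x_km": prev["pos"][-1][0], "y_km": prev["pos"][-1][1],
                })
                pending, gap_s = [seg], 0.0
            else:
                pending.append(seg)
                gap_s += gap
        trips.append(_finalize_trip(veh, pending, gap_s))
    trips_df = pd.DataFrame(trips)
    stops_df = pd.DataFrame(
        stops, columns=["vehicle_id", "t_off", "t_on", "x_km", "y_km"])
    return trips_df, stops_df


def correct_signal_loss(events: pd.DataFrame,
                        snap_threshold_km: float = SNAP_THRESHOLD_KM):
    """Snap implausible trip origins back to the previous stopping point.

    When the engine starts farther than ``snap_threshold_km`` from where it
    last stopped, the start position is unreliable (signal loss while
    parked indoors or during acquisition) and is replaced by the previous
    stop position, using the redundancy between consecutive events.
    Returns ``(corrected_events, n_corrections)``.
    """
    out = events.copy()
    n_corr = 0
    for _, ev in out.groupby("vehicle_id", sort=True):
        last_stop_pos = None
        for i in ev.index:
            kind = out.at[i, "kind"]
            if kind == "engine_stop":
                last_stop_pos = (out.at[i, "x_km"], out.at[i, "y_km"])
            elif kind == "engine_start" and last_stop_pos is not None:
                pos = (out.at[i, "x_km"], out.at[i, "y_km"])
                if _dist(np.array(pos), np.array(last_stop_pos)) \
                        > snap_threshold_km:
                    out.at[i, "x_km"], out.at[i, "y_km"] = last_stop_pos
                    n_corr += 1
    return out, n_corr


def filter_trips(trips: pd.DataFrame,
                 min_length_km: float = MIN_TRIP_LENGTH_KM,
                 min_duration_h: float = MIN_TRIP_DURATION_H) -> pd.DataFrame:
    """Keep trips strictly longer than 1 km and 5 min (very short trips
    never reach the base speed and carry no information about the model)."""
    keep = ((trips["path_length_km"] > min_length_km)
            & (trips["duration_h"] > min_duration_h))
    return trips.loc[keep].reset_index(drop=True)


def free_flow_speed(samples: pd.DataFrame, min_samples: int = 20,
                    percentile: float = 85.0) -> pd.DataFrame:
    """Per-road free-flow speed: the 85th percentile of observed speeds.

    The 85th percentile (linear interpolation between order statistics)
    approximates the uncongested night-time speed while discounting the
    fastest outlier drivers.  Roads with fewer than ``min_samples``
    observations are flagged ``low_confidence``; empty roads are omitted.
    """
    if not {"road_id", "speed_kmh"} <= set(samples.columns):
        raise ValueError("samples need road_id and speed_kmh columns")
    rows = []
    for road, grp in samples.groupby("road_id", sort=True):
        speeds = grp["speed_kmh"].to_numpy(dtype=float)
        if speeds.size == 0:
            warnings.warn(f"road {road!r} has no samples; omitted",
                          RuntimeWarning, stacklevel=2)
            continue
        rows.append({
            "road_id": road,
            "free_flow_kmh": float(np.percentile(speeds, percentile)),
            "n": int(speeds.size),
            "low_confidence": speeds.size < min_samples,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FreeFlowProfile:
    """Average relative free-flow speed along relative trip time."""

    rel_time: np.ndarray         # theta / t in [0, 1]
    curve: np.ndarray            # <v_free>(theta/t) / max
    n_trips: int
    n_skipped: int


def free_flow_profile(events: pd.DataFrame, trips: pd.DataFrame,
                      ff_table: pd.DataFrame, t_center_h: float,
                      half_width_h: float = 0.1,
                      n_grid: int = 21) -> FreeFlowProfile:
    """Aggregate the free-flow speed of the roads used along a trip.

    For every trip whose duration lies within ``t_center_h +/-
    half_width_h``, the per-fix road free-flow speeds are resampled onto a
    common relative-time grid theta/t in [0, 1]; curves are averaged across
    trips and normalized by the maximum of the average.  Trips whose fixes
    carry no road annotation are skipped (and counted).
    """
    if "road_id" not in events.columns:
        raise ValueError("events carry no road_id annotations")
    ff = ff_table.set_index("road_id")["free_flow_kmh"]
    grid = np.linspace(0.0, 1.0, n_grid)
    acc = np.zeros(n_grid)
    n_used = n_skipped = 0
    fixes = events[events["kind"] == "fix"]
    sel = trips[np.abs(trips["duration_h"] - t_center_h) <= half_width_h]
    for row in sel.itertuples(index=False):
        t_end = row.t_start + pd.Timedelta(hours=row.duration_h)
        f = fixes[(fixes["vehicle_id"] == row.vehicle_id)
                  & (fixes["timestamp"] >= row.t_start)
                  & (fixes["timestamp"] <= t_end)]
        f = f[f["road_id"].notna()]
        speeds = ff.reindex(f["road_id"]).to_numpy(dtype=float)
        ok = np.isfinite(speeds)
        if ok.sum() < 2:
            n_skipped += 1
            continue
        rel = ((f["timestamp"] - row.t_start) / pd.Timedelta(hours=1)
               ).to_numpy(dtype=float)[ok] / row.duration_h
        order = np.argsort(rel)
        acc += np.interp(grid, rel[order], speeds[ok][order])
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable trips in the requested duration window")
    curve = acc / n_used
    return FreeFlowProfile(rel_time=grid, curve=curve / curve.max(),
                           n_trips=n_used, n_skipped=n_skipped)


def assign_residence(stops: pd.DataFrame) -> pd.DataFrame:
    """Residence area per vehicle: the area collecting most parking time.

    ``stops`` must carry an ``area_id`` column.  Ties are broken by the
    earliest-observed area, with a warning.  Vehicles with no labelled
    stops are left unassigned (omitted).
    """
    if "area_id" not in stops.columns:
        raise ValueError("stops carry no area_id labels")
    labelled = stops[stops["area_id"].notna()].copy()
    labelled["park_h"] = ((labelled["t_on"] - labelled["t_off"])
                          / pd.Timedelta(hours=1))
    rows = []
    for veh, grp in labelled.groupby("vehicle_id", sort=True):
        totals = grp.groupby("area_id", sort=False)["park_h"].sum()
        best = totals.max()
        winners = totals[totals == best].index.tolist()
        if len(winners) > 1:
            warnings.warn(
                f"vehicle {veh!r}: parking-time tie between {winners}; "
                "keeping the earliest-observed area",
                RuntimeWarning, stacklevel=2)
            first_seen = grp.drop_duplicates("area_id")["area_id"].tolist()
            winners.sort(key=first_seen.index)
        rows.append({"vehicle_id": veh, "area_id": winners[0],
                     "park_h": float(best)})
    return pd.DataFrame(rows, columns=["vehicle_id", "area_id", "park_h"])
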