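"""Ground-truthed synthetic GPS fleet logs and trip tables.

The generator emulates the structure of insurance-style vehicular GPS
records — engine start/stop events with position fixes in between, emitted
every 2 km of travel (or every 30 s on top-layer roads), 10-30 m position
noise, micro-stop and signal-loss artifacts, exponential travel times and
lognormal rest times — so that the trip extractor and the fitting pipeline
can be exercised end-to-end against known ground truth without any real
data.

Geometry is deliberately minimal: every vehicle drives back and forth
along a straight east-west line through its home location.  The line
carries 2-km road segments labelled by transport layer, and 10-km square
municipality tiles provide area labels for residence assignment.  The
route is a carrier for road ids and positions, not a road-network model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as awio
from .params import KickModelParams, REFERENCE_PARAMS, MIN_TRIP_DURATION_H
from .simulate import (SpeedProfile, sample_durations, simulate_kick_profile,
                       simulate_population, trip_from_profile)

__all__ = [
    "SyntheticScenario",
    "generate_fleet_log",
    "generate_trip_table",
    "sample_rest_times",
    "area_label",
    "label_areas",
]

TILE_KM = 10.0
ROAD_SEGMENT_KM = 2.0
MICRO_STOP_GAP_S = 20.0


@dataclass(frozen=True)
class SyntheticScenario:
    """Configuration of one synthetic fleet."""

    n_vehicles: int = 20
    days: float = 2.0
    kick_params: KickModelParams = REFERENCE_PARAMS
    rest_median_h: float = 0.75          # lognormal median of away rests
    rest_sigma: float = 0.9              # lognormal shape
    rest_min_h: float = 0.1              # rests conditioned >= 6 min
    home_rest_factor: float = 4.0        # home rests are this much longer
    noise_sd_km: float = 0.02            # per-fix Gaussian position noise
    micro_stop_rate: float = 0.0         # per-trip probability
    signal_loss_rate: float = 0.0        # per-trip probability
    max_fix_spacing_km: float = 2.0
    highway_fix_dt_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("micro_stop_rate", "signal_loss_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        if self.noise_sd_km < 0:
            raise ValueError("noise_sd_km must be non-negative")
        if self.n_vehicles < 1 or self.days <= 0:
            raise ValueError("need n_vehicles >= 1 and days > 0")


def area_label(ix: int) -> str:
    """Spreadsheet-style label of tile column ix: A, B, ..., Z, AA, AB, ..."""
    if ix < 0:
        return "W" + area_label(-ix - 1)      # west of the origin
    label = ""
    ix += 1
    while ix > 0:
        ix, rem = divmod(ix - 1, 26)
        label = chr(65 + rem) + label
    return label


def label_areas(stops: pd.DataFrame, tile_km: float = TILE_KM) -> pd.DataFrame:
    """Attach municipality tile labels to a stop table by position."""
    out = stops.copy()
    out["area_id"] = [area_label(math.floor(x / tile_km))
                      for x in out["x_km"]]
    return out


def sample_rest_times(n: int, scenario: SyntheticScenario,
                      rng: np.random.Generator,
                      at_home: bool = False) -> np.ndarray:
    """Lognormal rest times (hours), conditioned on >= rest_min_h so that
    a rest is always long enough to terminate a trip."""
    median = scenario.rest_median_h * (scenario.home_rest_factor
                                       if at_home else 1.0)
    mu = math.log(median)
    out = rng.lognormal(mu, scenario.rest_sigma, size=n)
    while True:
        bad = out < scenario.rest_min_h
        if not bad.any():
            return out
        out[bad] = rng.lognormal(mu, scenario.rest_sigma, size=int(bad.sum()))


def _profile_fix_times(profile: SpeedProfile, params: KickModelParams,
                       max_spacing_km: float, highway_dt_s: float):
    """Times (hours, within the trip) at which the device emits a fix."""
    top_speed = params.v_cap
    times = []
    t = 0.0
    dist_acc = 0.0
    t_acc = 0.0
    highway_dt_h = highway_dt_s / 3600.0
    for i, width in enumerate(np.diff(profile.breakpoints)):
        v = profile.speeds[i]
        on_top = v >= top_speed
        remaining = width
        while remaining > 0:
            dt_dist = ((max_spacing_km - dist_acc) / v if v > 0 else math.inf)
            dt_time = (highway_dt_h - t_acc) if on_top else math.inf
            dt = min(dt_dist, dt_time)
            if dt >= remaining:
                dist_acc += v * remaining
                t_acc += remaining
                t += remaining
                remaining = 0.0
            else:
                t += dt
                remaining -= dt
                times.append(t)
                dist_acc = 0.0
                t_acc = 0.0
    return np.asarray(times)


def _cum_distance(profile: SpeedProfile, theta) -> np.ndarray:
    """Distance travelled along the profile by time theta (exact integral
    of the piecewise-constant speed)."""
    bp, sp = profile.breakpoints, profile.speeds
    cum = np.concatenate(([0.0], np.cumsum(sp * np.diff(bp))))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    idx = np.clip(np.searchsorted(bp, theta, side="right") - 1, 0,
                  sp.size - 1)
    return cum[idx] + sp[idx] * (theta - bp[idx])


def generate_fleet_log(scenario: SyntheticScenario):
    """Generate a fleet event log with full ground truth.

    Returns ``(events, truth)`` where ``events`` is the canonical event
    DataFrame (vehicle_id, timestamp, x_km, y_km, kind, road_id) and
    ``truth`` is a dict of DataFrames: ``trips`` (true trip records),
    ``rests`` (true rest intervals with area labels), ``artifacts`` (every
    injected micro-stop and signal-loss event) and ``residences`` (the
    planted home area per vehicle).
    """
    rng = np.random.default_rng(scenario.seed)
    params = scenario.kick_params
    t0_clock = pd.Timestamp("2011-05-01 07:00:00")
    horizon = t0_clock + pd.Timedelta(hours=24.0 * scenario.days)

    events, truth_trips, truth_rests, artifacts, residences = \
        [], [], [], [], []

    for vi in range(scenario.n_vehicles):
        veh = f"V{vi:04d}"
        home_x = 30.0 * vi
        residences.append({"vehicle_id": veh,
                           "area_id": area_label(
                               math.floor(home_x / TILE_KM))})
        clock = t0_clock + pd.Timedelta(
            minutes=float(rng.uniform(0.0, 60.0)))
        x = home_x
        prev_stop_exists = False
        outbound = True
        profile = None

        while clock < horizon:
            if outbound:
                t = float(sample_durations(1, params.t_bar, rng)[0])
                profile = simulate_kick_profile(t, params, rng)
                direction = 1.0
            else:
                # retrace the same route home: time-reversed copy
                t = profile.duration
                direction = -1.0
            trip_events, true_rec, trip_artifacts, x_end, clock_end = \
                _emit_trip(veh, clock, x, direction, profile, params,
                           scenario, rng,
                           allow_signal_loss=prev_stop_exists)
            events.extend(trip_events)
            truth_trips.append(true_rec)
            artifacts.extend(trip_artifacts)
            x, clock = x_end, clock_end
            prev_stop_exists = True

            at_home = not outbound
            rest_h = float(sample_rest_times(1, scenario, rng,
                                             at_home=at_home)[0])
            truth_rests.append({
                "vehicle_id": veh, "t_off": clock,
                "t_on": clock + pd.Timedelta(hours=rest_h),
                "x_km": x, "y_km": 0.0,
                "area_id": area_label(math.floor(x / TILE_KM)),
                "at_home": at_home,
            })
            clock += pd.Timedelta(hours=rest_h)
            outbound = not outbound

    events_df = pd.DataFrame(
        events, columns=["vehicle_id", "timestamp", "x_km", "y_km", "kind",
                         "road_id"])
    events_df = events_df.sort_values(["vehicle_id", "timestamp"],
                                      kind="stable").reset_index(drop=True)
    truth = {
        "trips": pd.DataFrame(truth_trips),
        "rests": pd.DataFrame(truth_rests),
        "artifacts": pd.DataFrame(
            artifacts, columns=["vehicle_id", "kind", "timestamp"]),
        "residences": pd.DataFrame(residences),
    }
    return events_df, truth


def _road_id(x: float, speed: float, params: KickModelParams) -> str:
    layer = int(round((speed - params.v0) / params.dv))
    seg = math.floor(x / ROAD_SEGMENT_KM)
    return f"L{layer}_S{seg}"


def _emit_trip(veh, clock, x0, direction, profile, params, scenario, rng,
               allow_signal_loss):
    """Emit the event rows of one trip; returns (events, true_record,
    artifacts, x_end, clock_end)."""
    t = profile.duration
    fix_times = _profile_fix_times(profile, params,
                                   scenario.max_fix_spacing_km,
                                   scenario.highway_fix_dt_s)
    path = float(_cum_distance(profile, t)[0])
    micro_stop_at = None
    if rng.uniform() < scenario.micro_stop_rate and t > 4.0 / 60.0:
        micro_stop_at = float(rng.uniform(0.3 * t, 0.7 * t))
    signal_loss = (allow_signal_loss
                   and rng.uniform() < scenario.signal_loss_rate)

    def pos_at(theta):
        d = float(_cum_distance(profile, theta)[0])
        return x0 + direction * d

    def noisy(x):
        return (x + rng.normal(0.0, scenario.noise_sd_km),
                rng.normal(0.0, scenario.noise_sd_km))

    gap_h = MICRO_STOP_GAP_S / 3600.0
    rows, artifacts = [], []

    start_x = x0
    if signal_loss:
        offset = float(rng.uniform(0.3, 1.0)) * float(rng.choice([-1, 1]))
        start_x = x0 + offset
        artifacts.append({"vehicle_id": veh, "kind": "signal_loss",
                          "timestamp": clock})
    rows.append((veh, clock, start_x, 0.0, "engine_start", None))

    def stamp(theta):
        shift = gap_h if (micro_stop_at is not None
                          and theta >= micro_stop_at) else 0.0
        return clock + pd.Timedelta(hours=theta + shift)

    emitted_micro = False
    for theta in fix_times:
        if (micro_stop_at is not None and not emitted_micro
                and theta >= micro_stop_at):
            xm = pos_at(micro_stop_at)
            tm = clock + pd.Timedelta(hours=micro_stop_at)
            rows.append((veh, tm, xm, 0.0, "engine_stop", None))
            rows.append((veh, tm + pd.Timedelta(seconds=MICRO_STOP_GAP_S),
                         xm, 0.0, "engine_start", None))
            artifacts.append({"vehicle_id": veh, "kind": "micro_stop",
                              "timestamp": tm})
            emitted_micro = True
        xt = pos_at(theta)
        nx, ny = noisy(xt)
        rows.append((veh, stamp(theta), nx, ny, "fix",
                     _road_id(xt, profile.speed_at(theta), params)))
    if micro_stop_at is not None and not emitted_micro:
        xm = pos_at(micro_stop_at)
        tm = clock + pd.Timedelta(hours=micro_stop_at)
        rows.append((veh, tm, xm, 0.0, "engine_stop", None))
        rows.append((veh, tm + pd.Timedelta(seconds=MICRO_STOP_GAP_S),
                     xm, 0.0, "engine_start", None))
        artifacts.append({"vehicle_id": veh, "kind": "micro_stop",
                          "timestamp": tm})

    x_end = pos_at(t)
    duration_true = t + (gap_h if micro_stop_at is not None else 0.0)
    clock_end = clock + pd.Timedelta(hours=duration_true)
    rows.append((veh, clock_end, x_end, 0.0, "engine_stop", None))

    true_rec = {
        "vehicle_id": veh, "t_start": clock, "duration_h": duration_true,
        "path_length_km": path, "mean_speed_kmh": path / duration_true,
        "direction": direction,
    }
    return rows, true_rec, artifacts, x_end, clock_end


def generate_trip_table(n: int, params: KickModelParams = REFERENCE_PARAMS,
                        seed: int = 0, mode: str = "eq_speed",
                        t_min: float = MIN_TRIP_DURATION_H,
                        path=None) -> pd.DataFrame:
    """Direct trip-level fixture: n trips from the kick model, optionally
    written as the canonical trip CSV."""
    rng = np.random.default_rng(seed)
    trips = simulate_population(n, params, rng, mode=mode, t_min=t_min)
    if path is not None:
        awio.write_trips(trips, path)
    return trips
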