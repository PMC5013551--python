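"""CSV/JSON I/O for trip tables, event logs, curves and run manifests.

Internal units are km, hours and km/h.  Trip tables use the canonical
columns (vehicle_id, t_start, duration_h, mean_speed_kmh, path_length_km);
event logs carry either planar ``x_km``/``y_km`` columns or geographic
``lon``/``lat`` columns, the latter converted to local planar km on read
with an equirectangular projection about the track centroid.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

TRIP_COLUMNS = ["vehicle_id", "t_start", "duration_h", "mean_speed_kmh",
                "path_length_km"]
EARTH_RADIUS_KM = 6371.0


def write_trips(trips: pd.DataFrame, path) -> None:
    cols = [c for c in TRIP_COLUMNS if c in trips.columns]
    cols += [c for c in trips.columns if c not in cols]
    trips.to_csv(path, index=False, columns=cols)


def read_trips(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["t_start"])
    missing = set(TRIP_COLUMNS) - set(df.columns) - {"t_start"}
    if missing:
        raise ValueError(f"{path}: trip table lacks columns "
                         f"{sorted(missing)}")
    return df


def load_filter_fixture() -> pd.DataFrame:
    """The packaged seven-trip table exercising the 1 km / 5 min filter
    (three survivors, with both boundaries represented exactly)."""
    from importlib.resources import files

    with (files("accelwalk") / "data" / "filter_fixture_trips.csv"
          ).open("rb") as fh:
        return pd.read_csv(fh, parse_dates=["t_start"])


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if {"lon", "lat"} <= set(df.columns):
        lat0 = np.deg2rad(df["lat"].mean())
        df["x_km"] = (np.deg2rad(df["lon"]) * EARTH_RADIUS_KM
                      * np.cos(lat0))
        df["y_km"] = np.deg2rad(df["lat"]) * EARTH_RADIUS_KM
    needed = {"vehicle_id", "timestamp", "x_km", "y_km", "kind"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: event log lacks columns "
                         f"{sorted(missing)}")
    if "road_id" not in df.columns:
        df["road_id"] = pd.NA
    return df


def write_ground_truth(truth: dict, path) -> None:
    payload = {k: json.loads(v.to_json(orient="split", date_format="iso"))
               for k, v in truth.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, *, command: str, config: dict, inputs=(),
                   outputs=(), seed=None) -> dict:
    """Record everything needed to reproduce a run: the command, its
    configuration, input/output hashes and the root seed."""
    from . import __version__

    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "outputs": {str(p): file_sha256(p) for p in outputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
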