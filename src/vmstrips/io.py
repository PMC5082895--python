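"""Plain-text readers/writers for the pipeline's artifact formats.

All artifacts are CSV or GeoJSON.  Fixed column names:

* VMS records: vessel_id, timestamp (UTC, ISO-8601), lat, lon
* ports: port_id, lat, lon, radius_nmi, region, start_nmi, start_min,
  end_nmi, end_min (constants blank for ordinary ports)
* observer trips: obs_trip_id, vessel_id, obs_start, obs_end
* fish tickets: ticket_id, vessel_id, fishing_start_date, landing_date,
  port, gear, stat_areas (';'-separated), program
* truth trips (synthetic only): vessel_id, trip_index, behavior,
  true_start, true_end, start_port, end_port, true_distance_nmi
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .synthetic_fleet import PortSet


def read_vms_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return df.sort_values(["vessel_id", "timestamp"]).reset_index(drop=True)


def write_vms_csv(records: pd.DataFrame, path):
    cols = [c for c in ("vessel_id", "timestamp", "lat", "lon")
            if c in records.columns]
    records[cols].to_csv(path, index=False)


def read_ports(path) -> PortSet:
    path = Path(path)
    if path.suffix == ".geojson":
        gj = json.loads(path.read_text())
        rows = []
        for feat in gj["features"]:
            props = dict(feat["properties"])
            geom = shape(feat["geometry"])
            props.setdefault("lon", geom.x)
            props.setdefault("lat", geom.y)
            rows.append(props)
        return PortSet.from_frame(pd.DataFrame(rows))
    return PortSet.from_frame(pd.read_csv(path))


def write_ports_csv(ports: PortSet, path):
    ports.to_frame().to_csv(path, index=False)


def read_stat_areas_geojson(path) -> dict:
    gj = json.loads(Path(path).read_text())
    return {feat["properties"]["area_id"]: shape(feat["geometry"])
            for feat in gj["features"]}


def write_stat_areas_geojson(areas: dict, path):
    gj = {"type": "FeatureCollection", "features": [
        {"type": "Feature", "properties": {"area_id": aid},
         "geometry": mapping(poly)} for aid, poly in areas.items()]}
    Path(path).write_text(json.dumps(gj))


def read_observer_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["obs_start", "obs_end"])


def read_tickets_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["fishing_start_date", "landing_date"])
    df["stat_areas"] = df["stat_areas"].fillna("").map(
        lambda s: [a for a in str(s).split(";") if a])
    return df


def write_tickets_csv(tickets: pd.DataFrame, path):
    out = tickets.copy()
    out["stat_areas"] = out["stat_areas"].map(";".join)
    out.to_csv(path, index=False)
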