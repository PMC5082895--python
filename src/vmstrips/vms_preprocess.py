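"""Cleaning and per-record field derivation for raw VMS streams.

Raw records carry (vessel_id, timestamp, lat, lon).  This module removes
duplicates, derives the kinematic and geographic fields everything
downstream relies on (inter-record distance, transmission interval,
apparent speed, nearest port and distance to it, statistical-area
membership), removes physically implausible fixes via an iterative
speed filter, and links records to observer trips.

Timestamps are treated as UTC throughout; convert on ingest if the
source is in another zone.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely

from .synthetic_fleet import PortSet

log = logging.getLogger(__name__)

DERIVED_COLUMNS = ("dist_prev_nmi", "interval_min", "speed_kn",
                   "nearest_port", "dist_port_nmi", "stat_area")


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Drop duplicate (vessel_id, timestamp) records, keeping the first.

    The result is sorted by vessel and timestamp.  Records sharing a
    timestamp but disagreeing on position are a data conflict: the first
    occurrence wins and the conflict is logged.
    """
    if records.empty:
        return records.copy()
    out = records.sort_values(["vessel_id", "timestamp"],
                              kind="stable").reset_index(drop=True)
    dup = out.duplicated(subset=["vessel_id", "timestamp"], keep="first")
    if dup.any():
        exact = out.duplicated(
            subset=["vessel_id", "timestamp", "lat", "lon"], keep="first")
        n_conflict = int((dup & ~exact).sum())
        if n_conflict:
            log.warning("%d duplicate-timestamp records with conflicting "
                        "positions; first occurrence kept", n_conflict)
        log.info("removed %d duplicate records", int(dup.sum()))
    return out.loc[~dup].reset_index(drop=True)


def _kinematics(out: pd.DataFrame) -> pd.DataFrame:
    """(Re)compute dist_prev_nmi / interval_min / speed_kn in place."""
    from . import geo
    g = out.groupby("vessel_id", sort=False)
    lat_p = g["lat"].shift()
    lon_p = g["lon"].shift()
    dt = (out["timestamp"] - g["timestamp"].shift()).dt.total_seconds() / 60.0
    dist = geo.haversine_nmi(lat_p, lon_p, out["lat"], out["lon"])
    out["dist_prev_nmi"] = np.asarray(dist)
    out["interval_min"] = dt
    with np.errstate(invalid="ignore", divide="ignore"):
        out["speed_kn"] = out["dist_prev_nmi"] / (out["interval_min"] / 60.0)
    return out


def assign_stat_areas(records: pd.DataFrame, areas: dict) -> pd.DataFrame:
    """Point-in-polygon stat-area membership (boundary counts as inside).

    Records outside every polygon get ``None``.
    """
    out = records.copy()
    lat = out["lat"].to_numpy()
    lon = out["lon"].to_numpy()
    assigned = np.full(len(out), None, dtype=object)
    unset = np.ones(len(out), dtype=bool)
    for aid, poly in areas.items():
        if not unset.any():
            break
        x0, y0, x1, y1 = poly.bounds
        cand = unset & (lon >= x0) & (lon <= x1) & (lat >= y0) & (lat <= y1)
        if not cand.any():
            continue
        shapely.prepare(poly)
        hit = shapely.intersects_xy(poly, lon[cand], lat[cand])
        idx = np.flatnonzero(cand)[hit]
        assigned[idx] = aid
        unset[idx] = False
    out["stat_area"] = assigned
    return out


def derive_fields(records: pd.DataFrame, ports: PortSet,
                  areas: dict | None = None) -> pd.DataFrame:
    """Derive per-record kinematic and geographic fields.

    Expects deduplicated, time-sorted input.  The first record of each
    vessel has NaN dist/interval/speed (there is no predecessor).  The
    operation is idempotent: derived columns are recomputed from the
    base columns every time.
    """
    out = records.copy()
    out = _kinematics(out)
    ids, dist = ports.nearest(out["lat"].to_numpy(), out["lon"].to_numpy())
    out["nearest_port"] = ids
    out["dist_port_nmi"] = dist
    if areas is not None:
        out = assign_stat_areas(out, areas)
    elif "stat_area" not in out.columns:
        out["stat_area"] = None
    return out


def filter_speed(records: pd.DataFrame, max_kn: float = 14.0,
                 max_iter: int = 200) -> pd.DataFrame:
    """Iteratively remove records implying speeds above ``max_kn``.

    Removing a record re-links its neighbours, which can expose new
    violations, so removal cascades until the chain is clean.  When a
    violating pair starts at the head of a vessel's stream the head
    itself may be the outlier; a look-ahead check decides which of the
    two records to drop.
    """
    out = records.copy()
    for _ in range(max_iter):
        out = _kinematics(out)
        speed = out["speed_kn"].to_numpy()
        bad = np.flatnonzero(speed > max_kn)
        if bad.size == 0:
            break
        drop = set()
        vessels_done = set()
        vid = out["vessel_id"].to_numpy()
        lat = out["lat"].to_numpy()
        lon = out["lon"].to_numpy()
        ts = out["timestamp"].to_numpy()
        first_of_vessel = np.r_[True, vid[1:] != vid[:-1]]
        for i in bad:
            v = vid[i]
            if v in vessels_done:
                continue  # one fix per vessel per pass; then re-derive
            vessels_done.add(v)
            if first_of_vessel[i - 1] and i + 1 < len(out) and vid[i + 1] == v:
                # violation right at the head: is the head the outlier?
                if (_pair_speed(lat, lon, ts, i, i + 1) <= max_kn
                        and _pair_speed(lat, lon, ts, i - 1, i + 1) > max_kn):
                    drop.add(i - 1)
                    continue
            drop.add(i)
        out = out.drop(out.index[sorted(drop)]).reset_index(drop=True)
        log.info("speed filter removed %d records", len(drop))
    else:
        raise RuntimeError("speed filter did not converge")
    return _kinematics(out)


def _pair_speed(lat, lon, ts, i, j):
    from . import geo
    d = float(geo.haversine_nmi(lat[i], lon[i], lat[j], lon[j]))
    dt_h = (ts[j] - ts[i]) / np.timedelta64(1, "h")
    return d / dt_h if dt_h > 0 else np.inf


def match_observer(records: pd.DataFrame,
                   observer: pd.DataFrame) -> pd.DataFrame:
    """Attach ``observed_trip_id`` where a record's timestamp falls within
    an observer-recorded trip (bounds inclusive).

    Observer intervals must be non-overlapping per vessel; overlapping
    intervals raise with the offending trip ids.
    """
    out = records.copy()
    out["observed_trip_id"] = None
    if observer.empty:
        return out
    for vessel, obs in observer.groupby("vessel_id"):
        obs = obs.sort_values("obs_start")
        starts = obs["obs_start"].to_numpy()
        ends = obs["obs_end"].to_numpy()
        overlap = starts[1:] <= ends[:-1]
        if overlap.any():
            k = np.flatnonzero(overlap)[0]
            bad = obs["obs_trip_id"].iloc[[k, k + 1]].tolist()
            raise ValueError(
                f"overlapping observer intervals for vessel {vessel!r}: {bad}")
        mask = out["vessel_id"] == vessel
        t = out.loc[mask, "timestamp"].to_numpy()
        k = np.searchsorted(starts, t, side="right") - 1
        ok = (k >= 0) & (t <= ends[np.clip(k, 0, len(ends) - 1)])
        ids = np.full(mask.sum(), None, dtype=object)
        ids[ok] = obs["obs_trip_id"].to_numpy()[k[ok]]
        out.loc[mask, "observed_trip_id"] = ids
    return out
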