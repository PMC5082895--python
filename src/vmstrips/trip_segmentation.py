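"""Partition vessel record streams into trips via in-port transitions.

A trip is a maximal run of at-sea records bracketed by in-port states.
The central difficulty is missing records: transmission gaps can hide
part or all of a port visit, so pure point-in-buffer logic is not enough.
In-port status therefore combines distance from port with speed and
dwell confirmation, declared transit corridors suppress spurious in-port
states between neighbouring hub ports, and long gaps are examined for a
plausible hidden port visit (flanking-geometry and speed-feasibility
checks) before being bridged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .synthetic_fleet import PortSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PortRule:
    """Per-port in-port confirmation constants.

    ``radius_nmi`` None means "use the port registry radius".  A run of
    within-radius records is confirmed in-port when any record moves at or
    below ``speed_ceiling_kn`` or the run dwells at least ``min_dwell_min``.
    """

    radius_nmi: float | None = None
    speed_ceiling_kn: float = 2.0
    min_dwell_min: float = 60.0


@dataclass
class PortRuleSet:
    """Rule constants for port-status assignment and trip segmentation.

    The exact per-port conditions used operationally are site-specific;
    they are exposed here as configuration rather than hard-coded.
    ``corridors`` is a list of ``(polygon, (port_id, ...))`` pairs marking
    non-fishing transit corridors: records inside the polygon are never
    in-port for those ports unless their speed confirms a stop.
    """

    rules: dict = field(default_factory=dict)  # port_id -> PortRule
    default: PortRule = field(default_factory=PortRule)
    #: hub visits involve multi-hour dock dwells that always produce
    #: near-zero-speed records, so dwell alone confirms a hub visit only
    #: when very long; this keeps slow fishing passes through the large
    #: buffers from triggering false port visits
    hub_min_dwell_min: float = 720.0
    gap_bridge_max_min: float = 240.0
    detour_max_nmi: float = 10.0
    min_visit_min: float = 30.0
    max_speed_kn: float = 14.0
    corridors: list = field(default_factory=list)

    def rule_for(self, port_id, ports: PortSet) -> PortRule:
        if port_id in self.rules:
            return self.rules[port_id]
        if ports[port_id].inport_constants:
            return PortRule(min_dwell_min=self.hub_min_dwell_min)
        return self.default

    def validate(self, ports: PortSet):
        unknown = [p for p in self.rules if p not in ports]
        if unknown:
            raise ValueError(f"rules reference unknown ports: {unknown}")


def dutch_akutan_corridor(ports: PortSet, width_deg=0.12, dock_clear_deg=0.05):
    """Default corridor polygon between the two hub ports of the toy layout."""
    a = ports["dutch_harbor"]
    b = ports["akutan"]
    line = shapely.LineString([(a.lon, a.lat), (b.lon, b.lat)])
    poly = line.buffer(width_deg)
    for p in (a, b):
        poly = poly.difference(shapely.Point(p.lon, p.lat).buffer(dock_clear_deg))
    return poly, ("dutch_harbor", "akutan")


@dataclass
class Trip:
    """An ordered run of at-sea records between two in-port states."""

    trip_id: str
    vessel_id: str
    record_index: np.ndarray  # positional indices into the records frame
    start_port: str | None
    end_port: str | None
    first_record_time: pd.Timestamp
    last_record_time: pd.Timestamp
    n_records: int
    max_gap_min: float
    start_port_inferred: bool = False
    end_port_inferred: bool = False
    start_time: pd.Timestamp | None = None  # post-adjustment (trip_metrics)
    end_time: pd.Timestamp | None = None
    duration_min: float | None = None
    distance_nmi: float | None = None
    duration_lower_bound: bool = False
    start_add_nmi: float = 0.0
    start_add_min: float = 0.0
    end_add_nmi: float = 0.0
    end_add_min: float = 0.0
    ticket_ids: list = field(default_factory=list)
    observed_trip_id: str | None = None
    label: str = "unclassified"  # afa_fishing | other_fishing | nonfishing | unclassified


def assign_port_status(records: pd.DataFrame, ports: PortSet,
                       rules: PortRuleSet) -> pd.DataFrame:
    """Add ``port_candidate`` and ``in_port`` columns.

    A record is a port candidate when it lies within its nearest port's
    (rule-constrained) radius; corridor polygons veto fast-moving
    candidates.  Candidate runs are then confirmed in-port at run level:
    any record at or below the speed ceiling, or total dwell at or above
    the minimum, confirms the whole run.  Records whose speed is
    undefined (stream heads) are neutral: they neither confirm nor
    disconfirm a stop.
    """
    rules.validate(ports)
    out = records.copy()
    lat = out["lat"].to_numpy()
    lon = out["lon"].to_numpy()
    speed = out["speed_kn"].to_numpy(dtype=float)
    nearest = out["nearest_port"].to_numpy()
    dist = out["dist_port_nmi"].to_numpy(dtype=float)

    radius = np.array([(rules.rule_for(p, ports).radius_nmi
                        or ports[p].radius_nmi) for p in nearest])
    ceiling = np.array([rules.rule_for(p, ports).speed_ceiling_kn
                        for p in nearest])
    candidate = np.where(dist <= radius, nearest, None)

    confirmed_slow = np.isfinite(speed) & (speed <= ceiling)
    veto_exempt = np.isnan(speed) | confirmed_slow
    for poly, corridor_ports in rules.corridors:
        shapely.prepare(poly)
        m = np.array([c in corridor_ports for c in candidate]) & ~veto_exempt
        if m.any():
            inside = shapely.intersects_xy(poly, lon[m], lat[m])
            idx = np.flatnonzero(m)[inside]
            candidate[idx] = None

    in_port = np.zeros(len(out), dtype=bool)
    vid = out["vessel_id"].to_numpy()
    ts = out["timestamp"].to_numpy()
    boundaries = np.flatnonzero(
        np.r_[True, (vid[1:] != vid[:-1]) | (candidate[1:] != candidate[:-1])])
    boundaries = np.r_[boundaries, len(out)]
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        port = candidate[a]
        if port is None:
            continue
        rule = rules.rule_for(port, ports)
        dwell = (ts[b - 1] - ts[a]) / np.timedelta64(1, "m")
        if confirmed_slow[a:b].any() or dwell >= rule.min_dwell_min:
            in_port[a:b] = True
    out["port_candidate"] = candidate
    out["in_port"] = in_port
    return out


def _infer_gap_port(lat_a, lon_a, t_a, lat_b, lon_b, t_b, ports: PortSet,
                    rules: PortRuleSet):
    """Candidate port for a hidden visit inside a long gap, or None.

    Accepts the port when either flanking fix is inside its buffer, or
    when the detour through the port barely lengthens the flight line and
    the gap leaves time to reach the port at a plausible speed and still
    pause there.
    """
    from . import geo
    best, best_detour = None, np.inf
    gap_min = (t_b - t_a) / np.timedelta64(1, "m")
    d_direct = float(geo.haversine_nmi(lat_a, lon_a, lat_b, lon_b))
    for p in ports:
        d_a = float(geo.haversine_nmi(lat_a, lon_a, p.lat, p.lon))
        d_b = float(geo.haversine_nmi(p.lat, p.lon, lat_b, lon_b))
        if d_a <= p.radius_nmi and d_b <= p.radius_nmi:
            return p.port_id
        detour = d_a + d_b - d_direct
        travel_min = (d_a + d_b) / rules.max_speed_kn * 60.0
        if (detour <= rules.detour_max_nmi
                and travel_min + rules.min_visit_min <= gap_min
                and detour < best_detour):
            best, best_detour = p.port_id, detour
    return best


def segment_trips(records: pd.DataFrame, ports: PortSet,
                  rules: PortRuleSet | None = None) -> list[Trip]:
    """Cut each vessel's stream into trips at in-port transitions.

    Consecutive in-port records collapse into port visits; maximal at-sea
    runs between visits become trips.  Within an at-sea run, any record
    gap longer than ``gap_bridge_max_min`` is tested for a hidden port
    visit and, when one is plausible, the run is split there with the
    inferred port shared between the two trips.  Every at-sea record
    belongs to exactly one trip.  A ``trip_id`` column is added to a copy
    of ``records`` available as ``segment_trips.last_assignment``.
    """
    rules = rules or PortRuleSet()
    if "in_port" not in records.columns:
        records = assign_port_status(records, ports, rules)
    trips = []
    assignment = np.full(len(records), None, dtype=object)
    pos_of = {label: i for i, label in enumerate(records.index)}
    for vessel, df in records.groupby("vessel_id", sort=False):
        pos = np.array([pos_of[i] for i in df.index])
        in_port = df["in_port"].to_numpy()
        cand = df["port_candidate"].to_numpy()
        ts = df["timestamp"].to_numpy()
        lat = df["lat"].to_numpy()
        lon = df["lon"].to_numpy()
        if in_port.all():
            continue
        # indices where at-sea runs start/end
        change = np.flatnonzero(np.r_[True, in_port[1:] != in_port[:-1]])
        change = np.r_[change, len(df)]
        for a, b in zip(change[:-1], change[1:]):
            if in_port[a]:
                continue
            start_port = cand[a - 1] if a > 0 else None
            end_port = cand[b] if b < len(df) else None
            # split the run at long gaps hiding a plausible port visit
            seg_start = a
            prev_port, prev_inferred = start_port, False
            intervals = (ts[a + 1:b] - ts[a:b - 1]) / np.timedelta64(1, "m") \
                if b - a > 1 else np.array([])
            for j in np.flatnonzero(intervals > rules.gap_bridge_max_min):
                i0, i1 = a + j, a + j + 1
                hidden = _infer_gap_port(lat[i0], lon[i0], ts[i0],
                                         lat[i1], lon[i1], ts[i1], ports, rules)
                if hidden is None:
                    continue
                seg = np.arange(seg_start, i0 + 1)
                trips.append(_make_trip(vessel, len(trips), records, pos[seg],
                                        ts, seg, prev_port, hidden,
                                        prev_inferred, True))
                assignment[pos[seg]] = trips[-1].trip_id
                seg_start = i1
                prev_port, prev_inferred = hidden, True
            seg = np.arange(seg_start, b)
            trips.append(_make_trip(vessel, len(trips), records, pos[seg], ts,
                                    seg, prev_port, end_port,
                                    prev_inferred, False))
            assignment[pos[seg]] = trips[-1].trip_id
    out = records.copy()
    out["trip_id"] = assignment
    segment_trips.last_assignment = out
    return trips


def _make_trip(vessel, k, records, positions, ts, seg, start_port, end_port,
               start_inferred, end_inferred) -> Trip:
    t = ts[seg]
    gaps = (t[1:] - t[:-1]) / np.timedelta64(1, "m") if len(t) > 1 else [0.0]
    return Trip(
        trip_id=f"{vessel}_t{k:04d}", vessel_id=vessel,
        record_index=positions,
        start_port=start_port, end_port=end_port,
        first_record_time=pd.Timestamp(t[0]), last_record_time=pd.Timestamp(t[-1]),
        n_records=len(seg), max_gap_min=float(np.max(gaps)),
        start_port_inferred=start_inferred, end_port_inferred=end_inferred)


def prune_short_trips(trips, min_records: int = 5):
    """Drop trips with fewer than ``min_records`` records (default: <= 4)."""
    kept = [t for t in trips if t.n_records >= min_records]
    n_dropped = len(trips) - len(kept)
    if n_dropped:
        log.info("pruned %d trips with <= %d records", n_dropped,
                 min_records - 1)
    return kept


def trips_to_frame(trips) -> pd.DataFrame:
    """One row per trip; list-valued fields serialized with ';'."""
    return pd.DataFrame([{
        "trip_id": t.trip_id, "vessel_id": t.vessel_id,
        "start_port": t.start_port, "end_port": t.end_port,
        "first_record_time": t.first_record_time,
        "last_record_time": t.last_record_time,
        "start_time": t.start_time, "end_time": t.end_time,
        "duration_min": t.duration_min, "distance_nmi": t.distance_nmi,
        "n_records": t.n_records, "max_gap_min": t.max_gap_min,
        "start_port_inferred": t.start_port_inferred,
        "end_port_inferred": t.end_port_inferred,
        "duration_lower_bound": t.duration_lower_bound,
        "ticket_ids": ";".join(t.ticket_ids),
        "observed_trip_id": t.observed_trip_id,
        "label": t.label,
    } for t in trips])
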