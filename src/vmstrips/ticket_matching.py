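"""Match fish tickets (landings reports) to VMS trips.

A ticket matches a trip when at least one of the trip's records lies in
one of the ticket's reported statistical areas on a date inside the
ticket's [fishing start, landing] window, for the same vessel.  Matched
tickets identify ports hidden by transmission gaps (with a 14-kn
speed-feasibility check on the assignment) and drive the AFA /
non-AFA partition of fishing trips.

Tickets carry calendar dates, not timestamps, so all window comparisons
are at day granularity with inclusive bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geo
from .synthetic_fleet import PortSet

log = logging.getLogger(__name__)

#: Pollock season calendar: winter "A", summer "B", "N" otherwise.
SEASONS = {"A": ((1, 1), (6, 9)), "B": ((6, 10), (10, 31))}


def season_of(ts) -> str:
    """Season letter for a timestamp/date: 'A', 'B' or 'N'."""
    ts = pd.Timestamp(ts)
    key = (ts.month, ts.day)
    for name, (lo, hi) in SEASONS.items():
        if lo <= key <= hi:
            return name
    return "N"


def match_tickets(trips, tickets: pd.DataFrame, records: pd.DataFrame):
    """Match tickets to trips; returns a (trip_id, ticket_id) DataFrame.

    Tickets whose landing date precedes their fishing start date are
    excluded and logged (documented data-entry errors).  A ticket
    matching several trips is resolved to the trip with the largest
    stat-area overlap, tie-broken by temporal proximity of the trip's
    last record to the landing date; a trip may match many tickets
    (multi-day / multi-processor offloads).  Matched ids are also stored
    on ``trip.ticket_ids``.
    """
    pairs = []
    if tickets.empty:
        return pd.DataFrame(columns=["trip_id", "ticket_id"])
    bad = tickets["landing_date"] < tickets["fishing_start_date"]
    if bad.any():
        log.warning("excluded %d tickets with landing date before fishing "
                    "start: %s", int(bad.sum()),
                    tickets.loc[bad, "ticket_id"].tolist())
    tickets = tickets.loc[~bad]
    trips_by_vessel = {}
    for t in trips:
        trips_by_vessel.setdefault(t.vessel_id, []).append(t)
    dates = records["timestamp"].dt.normalize().to_numpy()
    areas_col = records["stat_area"].to_numpy()
    for tk in tickets.itertuples():
        t_areas = set(tk.stat_areas)
        cands = []
        for trip in trips_by_vessel.get(tk.vessel_id, []):
            pos = trip.record_index
            in_window = ((dates[pos] >= np.datetime64(tk.fishing_start_date))
                         & (dates[pos] <= np.datetime64(tk.landing_date)))
            hit_areas = {a for a in areas_col[pos][in_window]
                         if a in t_areas}
            if hit_areas:
                prox = abs((trip.last_record_time.normalize()
                            - tk.landing_date).total_seconds())
                cands.append((len(hit_areas), -prox, trip))
        if not cands:
            continue
        cands.sort(key=lambda c: (c[0], c[1]), reverse=True)
        best = cands[0][2]
        pairs.append({"trip_id": best.trip_id, "ticket_id": tk.ticket_id})
        best.ticket_ids.append(tk.ticket_id)
    return pd.DataFrame(pairs, columns=["trip_id", "ticket_id"])


def backfill_ports(trip, ticket, flanking, ports: PortSet,
                   max_kn: float = 14.0):
    """Assign a gap-hidden end port from a matched ticket, with QA.

    ``flanking`` is ``(before, after)`` — the records (or None) on either
    side of the gap hiding the port visit, each a mapping with lat, lon
    and timestamp.  The implied speed needed to reach the ticket port
    from the flanking fixes within the available time must not exceed
    ``max_kn``; otherwise the nearest port to the final fix is assigned
    instead.  With no flanking records the port stays unknown.
    """
    before, after = flanking
    if before is None and after is None:
        return trip
    port_id = ticket["port"] if not isinstance(ticket, str) else ticket
    if port_id is None or port_id not in ports:
        return trip
    p = ports[port_id]
    feasible = True
    if before is not None and after is not None:
        d = (geo.haversine_nmi(before["lat"], before["lon"], p.lat, p.lon)
             + geo.haversine_nmi(p.lat, p.lon, after["lat"], after["lon"]))
        dt_h = (pd.Timestamp(after["timestamp"])
                - pd.Timestamp(before["timestamp"])).total_seconds() / 3600.0
        feasible = dt_h > 0 and float(d) / dt_h <= max_kn
    else:
        fix = before if before is not None else after
        ref_time = pd.Timestamp(ticket["landing_date"]) + pd.Timedelta(days=1) \
            if not isinstance(ticket, str) else None
        if ref_time is not None:
            d = float(geo.haversine_nmi(fix["lat"], fix["lon"], p.lat, p.lon))
            dt_h = abs((ref_time - pd.Timestamp(fix["timestamp"]))
                       .total_seconds()) / 3600.0
            feasible = dt_h > 0 and d / dt_h <= max_kn
    if feasible:
        trip.end_port = port_id
    else:
        fix = before if before is not None else after
        ids, _ = ports.nearest(fix["lat"], fix["lon"])
        trip.end_port = str(ids[0])
        log.info("trip %s: ticket port %r infeasible (> %s kn); nearest-port "
                 "fallback %r", trip.trip_id, port_id, max_kn, trip.end_port)
    trip.end_port_inferred = True
    return trip


@dataclass
class AfaConfig:
    """Spatial/seasonal filters for the AFA / non-AFA partition."""

    pollock_areas: set = field(default_factory=set)  # Bering Sea stat areas
    seasons: tuple = ("A", "B")


def partition_afa(trips, tickets: pd.DataFrame, records: pd.DataFrame,
                  config: AfaConfig | None = None):
    """Resolve fishing trips to AFA vs non-AFA.

    Ticket-matched fishing trips inherit the ticket's program.  Unmatched
    fishing trips use the monthly rule: if the vessel has no AFA tickets
    in the trip's landing month, the trip is non-AFA; otherwise it is AFA
    when it falls in a pollock season and touches the configured pollock
    grounds, else non-AFA.
    """
    config = config or AfaConfig()
    program_by_ticket = dict(zip(tickets.get("ticket_id", []),
                                 tickets.get("program", [])))
    afa_months = set()
    for tk in tickets.itertuples():
        if tk.program == "AFA":
            afa_months.add((tk.vessel_id, pd.Timestamp(tk.landing_date)
                            .to_period("M")))
    areas_col = records["stat_area"].to_numpy()
    for trip in trips:
        if trip.label not in ("fishing", "afa_fishing", "other_fishing"):
            continue
        programs = {program_by_ticket.get(t) for t in trip.ticket_ids}
        if "AFA" in programs:
            trip.label = "afa_fishing"
            continue
        if trip.ticket_ids:
            trip.label = "other_fishing"
            continue
        month = (trip.vessel_id, trip.last_record_time.to_period("M"))
        if month not in afa_months:
            trip.label = "other_fishing"
            continue
        in_season = season_of(trip.last_record_time) in config.seasons
        touches = any(a in config.pollock_areas
                      for a in areas_col[trip.record_index] if a is not None)
        trip.label = "afa_fishing" if (in_season and touches) else "other_fishing"
    return trips
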