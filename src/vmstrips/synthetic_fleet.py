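"""Ground-truthed synthetic fleets for exercising the trip pipeline.

Real VMS, observer and fish-ticket data for the North Pacific fleet are
confidential, so every downstream stage of this package is developed and
tested against fleets generated here.  The generator emulates the
statistical structure the pipeline assumes:

* continuous vessel tracks at 1-minute resolution, built from behavioral
  legs (port departure, open-water transit at 8-12 kn, slow sinuous
  trawling at 0.5-5 kn, near-drifting tender operations);
* VMS sampling at a nominal 30-min interval with a configurable fraction
  of 35-60 min jittered intervals (default 8.9%) and a fraction of longer
  gaps (default 2.1%) drawn from a discrete mixture;
* port dwell periods between trips, so the record stream contains the
  in-port runs the segmentation algorithm keys on;
* linked observer trip logs (with optional clock-error modes) and fish
  tickets (with optional date/field corruption).

All randomness flows through a single :class:`numpy.random.Generator`
passed explicitly, so fixtures are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box

from . import geo

HARBOR_SPEED_KN = 10.0  # steady speed inside large hub-port buffer zones
MIN_GROUND_PORT_NMI = 15.0  # fishing grounds are kept clear of port buffers


# ---------------------------------------------------------------------------
# Ports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PortSpec:
    """A named landing location with a detection radius.

    ``inport_constants`` — (start_nmi, start_min, end_nmi, end_min) — are
    the mean within-buffer travel distances/durations for large hub ports
    whose 10-nmi buffers hide substantial in-port transit.
    """

    port_id: str
    lat: float
    lon: float
    radius_nmi: float
    region: str = "Other"  # one of GOA, BS, AI, Other
    inport_constants: tuple[float, float, float, float] | None = None

    def __post_init__(self):
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValueError(f"invalid coordinates for port {self.port_id!r}")
        if not (0.0 < self.radius_nmi <= 10.0):
            raise ValueError(
                f"port {self.port_id!r}: radius must be in (0, 10] nmi")


class PortSet:
    """Indexed port registry supporting nearest-port queries."""

    def __init__(self, ports):
        ports = list(ports)
        if len(ports) < 2:
            raise ValueError("a port registry needs at least 2 ports")
        ids = [p.port_id for p in ports]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate port ids: {dupes}")
        self._ports = {p.port_id: p for p in ports}
        self._ids = np.array(ids)
        self._lat = np.array([p.lat for p in ports])
        self._lon = np.array([p.lon for p in ports])
        for i in range(len(ports)):
            for j in range(i + 1, len(ports)):
                d = float(geo.haversine_nmi(self._lat[i], self._lon[i],
                                            self._lat[j], self._lon[j]))
                if d < ports[i].radius_nmi + ports[j].radius_nmi:
                    warnings.warn(
                        f"ports {ids[i]!r} and {ids[j]!r} are {d:.1f} nmi apart; "
                        "their detection buffers overlap", stacklevel=2)

    def __iter__(self):
        return iter(self._ports.values())

    def __len__(self):
        return len(self._ports)

    def __contains__(self, port_id):
        return port_id in self._ports

    def __getitem__(self, port_id) -> PortSpec:
        return self._ports[port_id]

    @property
    def ids(self):
        return list(self._ports)

    def nearest(self, lat, lon):
        """Nearest port id(s) and distance(s) in nmi for query point(s)."""
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        d = geo.haversine_nmi(lat[:, None], lon[:, None],
                              self._lat[None, :], self._lon[None, :])
        k = np.argmin(d, axis=1)
        return self._ids[k], d[np.arange(len(lat)), k]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self:
            c = p.inport_constants or (np.nan,) * 4
            rows.append({"port_id": p.port_id, "lat": p.lat, "lon": p.lon,
                         "radius_nmi": p.radius_nmi, "region": p.region,
                         "start_nmi": c[0], "start_min": c[1],
                         "end_nmi": c[2], "end_min": c[3]})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PortSet":
        ports = []
        for row in df.itertuples():
            const = None
            if not pd.isna(getattr(row, "start_nmi", np.nan)):
                const = (row.start_nmi, row.start_min, row.end_nmi, row.end_min)
            ports.append(PortSpec(row.port_id, row.lat, row.lon,
                                  row.radius_nmi, getattr(row, "region", "Other"),
                                  const))
        return cls(ports)


#: A two-hub layout mimicking the Dutch Harbor / Akutan geography plus
#: smaller, more exposed ports with constrained radii.
BERING_TOY = (
    PortSpec("dutch_harbor", 53.8898, -166.5422, 10.0, "AI",
             inport_constants=(10.0, 80.0, 10.0, 80.0)),
    PortSpec("akutan", 54.1325, -165.7854, 10.0, "AI",
             inport_constants=(13.0, 101.0, 12.0, 92.0)),
    PortSpec("kodiak", 57.7900, -152.4100, 5.0, "GOA"),
    PortSpec("sand_point", 55.3370, -160.4970, 3.0, "GOA"),
    PortSpec("port_moller", 55.9860, -160.5620, 3.0, "BS"),
)

_PRESETS = {"bering_toy": BERING_TOY}


def build_port_registry(config) -> PortSet:
    """Build a :class:`PortSet` from a preset name or a list of PortSpec."""
    if isinstance(config, str):
        try:
            config = _PRESETS[config]
        except KeyError:
            raise ValueError(f"unknown port preset {config!r}") from None
    return PortSet(config)


# ---------------------------------------------------------------------------
# Statistical management areas
# ---------------------------------------------------------------------------

def build_stat_areas(lat_range=(52.0, 62.0), lon_range=(-172.0, -150.0),
                     dlat=1.0, dlon=2.0):
    """Rectangular grid of statistical management areas as shapely polygons.

    Returns ``{area_id: Polygon}``; ids encode the cell's SW corner.
    """
    areas = {}
    lat0, lat1 = lat_range
    lon0, lon1 = lon_range
    for la in np.arange(lat0, lat1, dlat):
        for lo in np.arange(lon0, lon1, dlon):
            aid = f"SA{int(round(la)):02d}{int(round(abs(lo))):03d}"
            areas[aid] = box(lo, la, lo + dlon, la + dlat)
    return areas


def default_fishing_areas(areas) -> list[str]:
    """Area ids overlapping the toy pollock grounds (Bering side)."""
    grounds = box(-170.0, 52.0, -158.0, 59.0)
    return sorted(a for a, poly in areas.items() if poly.intersects(grounds))


# ---------------------------------------------------------------------------
# Sampling model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingModel:
    """VMS transmission model: nominal interval, jitter and gap mixture."""

    nominal_interval_min: int = 30
    jitter_fraction_35_60: float = 0.089
    long_gap_fraction: float = 0.021
    gap_lengths_min: tuple[int, ...] = (60, 90, 120, 150, 240, 480)
    gap_weights: tuple[float, ...] = (0.35, 0.25, 0.15, 0.10, 0.10, 0.05)

    def __post_init__(self):
        for f in (self.jitter_fraction_35_60, self.long_gap_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("sampling fractions must lie in [0, 1]")
        if self.jitter_fraction_35_60 + self.long_gap_fraction > 1.0:
            raise ValueError("sampling fractions must sum to at most 1")
        if len(self.gap_lengths_min) != len(self.gap_weights):
            raise ValueError("gap_lengths_min and gap_weights differ in length")
        if self.nominal_interval_min < 1:
            raise ValueError("nominal interval must be >= 1 min")


# ---------------------------------------------------------------------------
# Tracks and truth
# ---------------------------------------------------------------------------

@dataclass
class VesselTrack:
    """One vessel's continuous 1-minute track (positions + behavioral state)."""

    vessel_id: str
    t0: pd.Timestamp
    lat: np.ndarray
    lon: np.ndarray
    state: np.ndarray  # 'dock' | 'transit' | 'fishing' | 'drift'

    def times(self):
        return self.t0 + pd.to_timedelta(np.arange(len(self.lat)), unit="min")


@dataclass(frozen=True)
class TripPlan:
    behavior: str  # afa_fishing | other_fishing | transit | tender
    start_port: str
    end_port: str
    t0: pd.Timestamp
    duration_hr: float | None = None
    speed_kn: float | None = None


@dataclass
class TruthTrip:
    vessel_id: str
    trip_index: int
    behavior: str
    true_start: pd.Timestamp
    true_end: pd.Timestamp
    start_port: str
    end_port: str
    true_distance_nmi: float
    fishing_start: pd.Timestamp | None = None


def _straight_leg(ports: PortSet, lat_a, lon_a, lat_b, lon_b, cruise_kn,
                  zone_a_nmi=0.0, zone_b_nmi=0.0):
    """1-min points along the great circle a->b (excluding the start point).

    Speed is ``HARBOR_SPEED_KN`` inside the start/end harbor zones and
    ``cruise_kn`` elsewhere; the final point is snapped exactly to b.
    """
    total = float(geo.haversine_nmi(lat_a, lon_a, lat_b, lon_b))
    if total < 1e-9:
        return np.array([lat_b]), np.array([lon_b])
    cum = []
    d = 0.0
    while d < total - 1e-9:
        if d < zone_a_nmi or total - d < zone_b_nmi:
            v = HARBOR_SPEED_KN
        else:
            v = cruise_kn
        d = min(d + v / 60.0, total)
        cum.append(d)
    fracs = np.asarray(cum) / total
    return geo.gc_interpolate(lat_a, lon_a, lat_b, lon_b, fracs)


def _wander_bout(lat0, lon0, minutes, speed_range, speed_sd, turn_sd_deg,
                 leg_minutes, rng, leg_turn_deg=120.0):
    """Sinuous slow-speed bout on a local tangent plane (1-min steps).

    Returns per-minute (lat, lon) excluding the start point.  The local
    flat-Earth approximation is adequate for bouts spanning tens of nmi;
    path lengths are always re-measured with the haversine afterwards.
    """
    speeds = np.empty(minutes)
    turns = rng.normal(0.0, turn_sd_deg, minutes)
    t = 0
    heading = rng.uniform(0.0, 360.0)
    headings = np.empty(minutes)
    while t < minutes:
        n = min(int(rng.uniform(*leg_minutes)), minutes - t)
        base = rng.uniform(*speed_range)
        speeds[t:t + n] = np.clip(base + rng.normal(0.0, speed_sd, n),
                                  max(0.02, speed_range[0] / 5), 5.0)
        # leg-level course change; wide ranges produce hairpin reversals
        turns[t] += rng.uniform(-leg_turn_deg, leg_turn_deg)
        t += n
    headings[:] = (heading + np.cumsum(turns)) % 360.0
    step = speeds / 60.0
    th = np.radians(headings)
    dx = np.cumsum(step * np.sin(th))
    dy = np.cumsum(step * np.cos(th))
    lat = lat0 + dy / 60.0
    lon = lon0 + dx / (60.0 * np.cos(np.radians(lat0)))
    return lat, lon


def _tow_leg(lat0, lon0, heading, minutes, rng):
    """One straight-ish trawl tow on a local tangent plane (1-min steps)."""
    speeds = np.clip(rng.uniform(2.5, 4.5) + rng.normal(0.0, 0.3, minutes),
                     0.5, 5.0)
    headings = heading + np.cumsum(rng.normal(0.0, 3.0, minutes))
    step = speeds / 60.0
    th = np.radians(headings)
    dx = np.cumsum(step * np.sin(th))
    dy = np.cumsum(step * np.cos(th))
    lat = lat0 + dy / 60.0
    lon = lon0 + dx / (60.0 * np.cos(np.radians(lat0)))
    return lat, lon, float(headings[-1])


def _pick_ground(ports: PortSet, port: PortSpec, dist_range, rng):
    for _ in range(50):
        brg = rng.uniform(0.0, 360.0)
        dist = rng.uniform(*dist_range)
        la, lo = geo.destination(port.lat, port.lon, brg, dist)
        _, dmin = ports.nearest(la, lo)
        if dmin[0] >= MIN_GROUND_PORT_NMI:
            return float(la), float(lo)
    raise RuntimeError("could not place a fishing ground clear of all ports")


def simulate_trip(vessel_id, plan: TripPlan, ports: PortSet,
                  rng: np.random.Generator):
    """Simulate one trip; returns ``(TruthTrip, (lat, lon, state))``.

    The returned arrays are at 1-min resolution, starting and ending at the
    dock coordinates of the start/end ports.  ``true_distance_nmi`` is the
    haversine length of the 1-min polyline.
    """
    if plan.duration_hr is not None and plan.duration_hr <= 0:
        raise ValueError("plan duration must be positive")
    a = ports[plan.start_port]
    b = ports[plan.end_port]
    zone_a = a.radius_nmi if a.inport_constants else 0.0
    zone_b = b.radius_nmi if b.inport_constants else 0.0
    lats = [np.array([a.lat])]
    lons = [np.array([a.lon])]
    states = [np.array(["dock"])]

    def _append(la, lo, st):
        lats.append(np.asarray(la))
        lons.append(np.asarray(lo))
        states.append(np.full(len(np.asarray(la)), st))

    if plan.behavior == "transit":
        dist = float(geo.haversine_nmi(a.lat, a.lon, b.lat, b.lon))
        speed = plan.speed_kn if plan.speed_kn is not None else rng.uniform(8.0, 12.0)
        if plan.duration_hr is not None and dist / 12.0 > plan.duration_hr:
            raise ValueError(
                f"port {plan.end_port!r} unreachable from {plan.start_port!r} "
                f"at 12 kn within {plan.duration_hr} h")
        la, lo = _straight_leg(ports, a.lat, a.lon, b.lat, b.lon, speed,
                               zone_a, zone_b)
        _append(la, lo, "transit")
        fishing_start = None
    elif plan.behavior in ("afa_fishing", "other_fishing", "tender"):
        if plan.duration_hr is None:
            raise ValueError(f"{plan.behavior} plans require a duration")
        budget = plan.duration_hr * 60.0
        cruise = plan.speed_kn if plan.speed_kn is not None else rng.uniform(8.0, 12.0)
        tender = plan.behavior == "tender"
        # grounds sit on the shelf edge near the ports (closer for the
        # pollock fleet, wider-ranging for other fisheries)
        dist_range = {"tender": (20.0, 60.0),
                      "afa_fishing": (20.0, 60.0),
                      "other_fishing": (30.0, 120.0)}[plan.behavior]
        gla, glo = _pick_ground(ports, a, dist_range, rng)
        la, lo = _straight_leg(ports, a.lat, a.lon, gla, glo, cruise, zone_a, 0.0)
        _append(la, lo, "transit")
        fishing_start = len(np.concatenate(lats)) - 1
        cur_la, cur_lo = float(la[-1]), float(lo[-1])
        elapsed = fishing_start
        state = "drift" if tender else "fishing"
        tow_heading = rng.uniform(0.0, 360.0)
        first = True
        while True:
            ret_est = float(geo.haversine_nmi(cur_la, cur_lo, b.lat, b.lon)) \
                / cruise * 60.0 + 15.0
            leg_min = int(rng.uniform(60, 180))
            if not first and elapsed + leg_min + ret_est > budget:
                break
            # the fleet works open grounds: bouts keep clear of harbor
            # approaches, which vessels only enter to land
            leg_state = state
            placed = False
            for _ in range(8):
                if tender:
                    wla, wlo = _wander_bout(cur_la, cur_lo, leg_min,
                                            (0.1, 0.6), 0.05, 8.0, (30, 90), rng)
                elif not first and rng.random() < 0.2:
                    # fast move to a fresh tow line, often doubling back;
                    # sharp course reversals at cruise speed dominate the
                    # distance hidden by transmission gaps
                    leg_min = int(rng.uniform(30, 90))
                    wla, wlo = _wander_bout(cur_la, cur_lo, leg_min,
                                            (8.0, 12.0), 0.2, 2.0,
                                            (30, 90), rng, leg_turn_deg=180.0)
                    leg_state = "transit"
                else:
                    # lawnmower tow pattern: straight tows with ~180
                    # degree reversals between successive tows
                    wla, wlo, end_heading = _tow_leg(cur_la, cur_lo,
                                                     tow_heading, leg_min, rng)
                    tow_heading = end_heading + 180.0 + rng.normal(0.0, 25.0)
                _, dmin = ports.nearest(wla[::10], wlo[::10])
                if dmin.min() >= MIN_GROUND_PORT_NMI - 3.0:
                    placed = True
                    break
                tow_heading = rng.uniform(0.0, 360.0)
            if not placed:
                # crowded corner of the ground: steam radially away from
                # the nearest port before resuming
                pid, _ = ports.nearest(cur_la, cur_lo)
                p = ports[pid[0]]
                brg = float(geo.initial_bearing_deg(p.lat, p.lon,
                                                    cur_la, cur_lo))
                wla, wlo, eh = _tow_leg(cur_la, cur_lo, brg, leg_min, rng)
                tow_heading = eh + rng.normal(0.0, 25.0)
                leg_state = state
            _append(wla, wlo, leg_state)
            cur_la, cur_lo = float(wla[-1]), float(wlo[-1])
            elapsed += leg_min
            first = False
        la, lo = _straight_leg(ports, cur_la, cur_lo, b.lat, b.lon, cruise,
                               0.0, zone_b)
        _append(la, lo, "transit")
    else:
        raise ValueError(f"unknown behavior {plan.behavior!r}")

    lat = np.concatenate(lats)
    lon = np.concatenate(lons)
    state = np.concatenate(states)
    n = len(lat)
    fs = plan.t0 + pd.Timedelta(minutes=int(fishing_start)) \
        if fishing_start is not None else None
    truth = TruthTrip(
        vessel_id=vessel_id, trip_index=-1, behavior=plan.behavior,
        true_start=plan.t0, true_end=plan.t0 + pd.Timedelta(minutes=n - 1),
        start_port=plan.start_port, end_port=plan.end_port,
        true_distance_nmi=geo.polyline_nmi(lat, lon), fishing_start=fs)
    return truth, (lat, lon, state)


# ---------------------------------------------------------------------------
# VMS sampling
# ---------------------------------------------------------------------------

def sample_vms(track: VesselTrack, model: SamplingModel,
               rng: np.random.Generator) -> pd.DataFrame:
    """Sample VMS records from a 1-min track.

    Records carry only (vessel_id, timestamp, lat, lon); every emitted
    position is a point of the generating track.
    """
    n = len(track.lat)
    gap_lengths = np.asarray(model.gap_lengths_min)
    gap_w = np.asarray(model.gap_weights, dtype=float)
    gap_w = gap_w / gap_w.sum()
    offsets = [0]
    t = 0
    while t < n - 1:
        u = rng.random()
        if u < model.long_gap_fraction:
            iv = int(rng.choice(gap_lengths, p=gap_w))
        elif u < model.long_gap_fraction + model.jitter_fraction_35_60:
            iv = int(rng.integers(35, 61))
        else:
            iv = model.nominal_interval_min
        t += iv
        if t <= n - 1:
            offsets.append(t)
        else:
            break
    idx = np.asarray(offsets)
    return pd.DataFrame({
        "vessel_id": track.vessel_id,
        "timestamp": track.t0 + pd.to_timedelta(idx, unit="min"),
        "lat": track.lat[idx],
        "lon": track.lon[idx],
    })


# ---------------------------------------------------------------------------
# Observer and fish-ticket emission
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClockErrorModel:
    """Observer clock-error model.

    ``p_dock_start`` injects the documented mode where the observed trip
    starts while the vessel is still at the dock (observed trip too long);
    ``p_late_start`` the mode where the trip starts when the vessel is
    already hours outside of port (observed trip too short).
    """

    sd_min: float = 0.0
    p_dock_start: float = 0.0
    dock_start_min: float = 120.0
    p_late_start: float = 0.0
    late_start_min: float = 120.0


def emit_observer_records(truth, coverage, clock_error: ClockErrorModel | None,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Observer trip log: one row per observed truth trip.

    ``truth`` is a DataFrame of truth trips; ``coverage`` is the per-trip
    observation probability.
    """
    if not (0.0 <= coverage <= 1.0):
        raise ValueError("coverage must lie in [0, 1]")
    ce = clock_error or ClockErrorModel()
    rows = []
    for i, row in enumerate(truth.itertuples()):
        if rng.random() >= coverage:
            continue
        start = row.true_start
        end = row.true_end
        u = rng.random()
        if u < ce.p_dock_start:
            start = start - pd.Timedelta(minutes=ce.dock_start_min)
        elif u < ce.p_dock_start + ce.p_late_start:
            start = start + pd.Timedelta(minutes=ce.late_start_min)
        if ce.sd_min > 0:
            start = start + pd.Timedelta(minutes=round(rng.normal(0, ce.sd_min)))
            end = end + pd.Timedelta(minutes=round(rng.normal(0, ce.sd_min)))
        rows.append({"obs_trip_id": f"obs_{row.vessel_id}_{i:04d}",
                     "vessel_id": row.vessel_id,
                     "obs_start": start, "obs_end": end,
                     "truth_index": i})
    return pd.DataFrame(rows, columns=["obs_trip_id", "vessel_id", "obs_start",
                                       "obs_end", "truth_index"])


@dataclass(frozen=True)
class TicketErrorModel:
    """Fish-ticket corruption model (error injection is the point)."""

    p_drop: float = 0.0        # landing never reported
    p_date_swap: float = 0.0   # landing/fishing-start dates transposed
    p_blank_port: float = 0.0  # port field left blank


_GEAR_OTHER = ("bottom_trawl", "longline", "pot")


def emit_fish_tickets(truth, tracks, stat_areas, error_model, rng) -> pd.DataFrame:
    """Fish tickets for fishing truth trips.

    The ticket date window spans [fishing start date, landing date], the
    stat areas are those overlapped by the fishing portion of the track,
    and the port is the trip's end port; the error model can corrupt these.
    """
    em = error_model or TicketErrorModel()
    area_items = []
    for aid, p in stat_areas.items():
        shapely.prepare(p)
        area_items.append((aid, p.bounds))
    rows = []
    k = 0
    for i, row in enumerate(truth.itertuples()):
        if row.behavior not in ("afa_fishing", "other_fishing"):
            continue
        if rng.random() < em.p_drop:
            continue
        track = tracks[row.vessel_id]
        t_rel0 = int((row.true_start - track.t0).total_seconds() // 60)
        t_rel1 = int((row.true_end - track.t0).total_seconds() // 60)
        seg = slice(t_rel0, t_rel1 + 1)
        fishing = np.isin(track.state[seg], ("fishing", "drift"))
        la = track.lat[seg][fishing][::30]
        lo = track.lon[seg][fishing][::30]
        aids = set()
        for aid, (x0, y0, x1, y1) in area_items:
            m = (lo >= x0) & (lo <= x1) & (la >= y0) & (la <= y1)
            if m.any() and shapely.intersects_xy(stat_areas[aid], lo[m], la[m]).any():
                aids.add(aid)
        fs = row.fishing_start
        start_date = (row.true_start if pd.isna(fs) else fs).date()
        landing_date = row.true_end.date()
        if rng.random() < em.p_date_swap and landing_date != start_date:
            start_date, landing_date = landing_date, start_date
        port = row.end_port
        if rng.random() < em.p_blank_port:
            port = None
        afa = row.behavior == "afa_fishing"
        rows.append({
            "ticket_id": f"tk{k:05d}", "vessel_id": row.vessel_id,
            "fishing_start_date": pd.Timestamp(start_date),
            "landing_date": pd.Timestamp(landing_date),
            "port": port,
            "gear": "pelagic_trawl" if afa else str(rng.choice(_GEAR_OTHER)),
            "stat_areas": sorted(aids),
            "program": "AFA" if afa else "other",
            "truth_index": i,
        })
        k += 1
    return pd.DataFrame(rows, columns=["ticket_id", "vessel_id",
                                       "fishing_start_date", "landing_date",
                                       "port", "gear", "stat_areas", "program",
                                       "truth_index"])


# ---------------------------------------------------------------------------
# Whole-fleet simulation
# ---------------------------------------------------------------------------

@dataclass
class FleetConfig:
    """Study conditions for a synthetic fleet.

    Defaults emulate the Bering Sea pollock catcher-vessel fleet: pollock
    trips of 1-4 days, longer non-pollock trips, transits between ports,
    occasional tendering; 30-min VMS sampling with the observed 8.9% /
    2.1% jitter/gap mix; full observer coverage with exact clocks.
    """

    n_vessels: int = 25
    trips_per_vessel: int = 20
    start: pd.Timestamp = pd.Timestamp("2013-01-05")
    stagger_days: float = 240.0
    behavior_mix: dict = field(default_factory=lambda: {
        "afa_fishing": 0.45, "other_fishing": 0.15,
        "transit": 0.30, "tender": 0.10})
    afa_duration_days: tuple = (1.0, 4.0)
    other_duration_days: tuple = (1.0, 6.0)
    tender_duration_days: tuple = (0.5, 1.5)
    dwell_hr: tuple = (4.0, 12.0)
    sampling: SamplingModel = field(default_factory=SamplingModel)
    observer_coverage: float = 1.0
    clock_error: ClockErrorModel = field(default_factory=ClockErrorModel)
    ticket_errors: TicketErrorModel = field(default_factory=TicketErrorModel)
    #: share of tendering assignments known from processor calendars
    #: (feeds the non-fishing decision rule; the rest are left for the
    #: classification model, as with research charters in practice)
    tender_calendar_coverage: float = 0.8
    ports: str = "bering_toy"

    @classmethod
    def from_dict(cls, d: dict) -> "FleetConfig":
        """Build from a plain mapping (e.g. parsed YAML)."""
        d = dict(d or {})
        sub = {"sampling": SamplingModel, "clock_error": ClockErrorModel,
               "ticket_errors": TicketErrorModel}
        kwargs = {}
        for k, v in d.items():
            if k in sub and isinstance(v, dict):
                kwargs[k] = sub[k](**v)
            elif k == "start":
                kwargs[k] = pd.Timestamp(v)
            elif k in ("dwell_hr", "afa_duration_days", "other_duration_days",
                       "tender_duration_days") and isinstance(v, list):
                kwargs[k] = tuple(v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


@dataclass
class FleetData:
    ports: PortSet
    stat_areas: dict
    fishing_areas: list
    truth: pd.DataFrame
    tracks: dict
    records: pd.DataFrame
    observer: pd.DataFrame
    tickets: pd.DataFrame
    #: known tendering periods: (vessel_id, start, end) tuples
    tender_calendar: list = field(default_factory=list)


_HOME_PORTS = (("dutch_harbor", 0.6), ("akutan", 0.25), ("kodiak", 0.15))


def _truth_frame(trips) -> pd.DataFrame:
    return pd.DataFrame([{
        "vessel_id": t.vessel_id, "trip_index": t.trip_index,
        "behavior": t.behavior, "true_start": t.true_start,
        "true_end": t.true_end, "start_port": t.start_port,
        "end_port": t.end_port, "true_distance_nmi": t.true_distance_nmi,
        "fishing_start": t.fishing_start,
    } for t in trips])


def _in_pollock_season(ts) -> bool:
    from .ticket_matching import season_of
    return season_of(ts) in ("A", "B")


def simulate_fleet(config: FleetConfig, rng: np.random.Generator) -> FleetData:
    """Simulate a full fleet: tracks, truth trips, VMS, observers, tickets."""
    ports = build_port_registry(config.ports)
    areas = build_stat_areas()
    fishing_areas = default_fishing_areas(areas)
    behaviors = list(config.behavior_mix)
    bweights = np.array([config.behavior_mix[b] for b in behaviors], dtype=float)
    bweights = bweights / bweights.sum()
    home_ids = [h for h, _ in _HOME_PORTS]
    home_w = np.array([w for _, w in _HOME_PORTS])

    truth_rows = []
    tracks = {}
    rec_frames = []
    for v in range(config.n_vessels):
        vessel_id = f"V{v:03d}"
        home = str(rng.choice(home_ids, p=home_w / home_w.sum()))
        t = config.start + pd.Timedelta(
            minutes=int(rng.uniform(0, config.stagger_days * 24 * 60)))
        cur_port = home
        lat_parts, lon_parts, state_parts = [], [], []
        t0_vessel = t
        n_accum = 0
        for k in range(config.trips_per_vessel):
            # dwell at the dock before the trip
            dwell = int(rng.uniform(*config.dwell_hr) * 60)
            p = ports[cur_port]
            lat_parts.append(np.full(dwell, p.lat))
            lon_parts.append(np.full(dwell, p.lon))
            state_parts.append(np.full(dwell, "dock"))
            n_accum += dwell
            t_trip = t0_vessel + pd.Timedelta(minutes=n_accum)

            behavior = str(rng.choice(behaviors, p=bweights))
            if behavior == "afa_fishing" and not _in_pollock_season(t_trip):
                behavior = "other_fishing"
            if behavior == "transit":
                others = [pid for pid in ports.ids if pid != cur_port]
                w = np.array([3.0 if ports[o].inport_constants else 1.0
                              for o in others])
                end_port = str(rng.choice(others, p=w / w.sum()))
                dur = None
            else:
                end_port = cur_port if rng.random() < 0.85 else str(
                    rng.choice([pid for pid in ports.ids if pid != cur_port]))
                rngs = {"afa_fishing": config.afa_duration_days,
                        "other_fishing": config.other_duration_days,
                        "tender": config.tender_duration_days}[behavior]
                dur = rng.uniform(*rngs) * 24.0
            plan = TripPlan(behavior, cur_port, end_port, t_trip, duration_hr=dur)
            truth, (la, lo, st) = simulate_trip(vessel_id, plan, ports, rng)
            truth.trip_index = k
            truth_rows.append(truth)
            # skip the duplicated dock point at the trip start
            lat_parts.append(la[1:])
            lon_parts.append(lo[1:])
            state_parts.append(st[1:])
            n_accum += len(la) - 1
            cur_port = end_port
        # trailing dwell so the final port visit is observable
        dwell = int(rng.uniform(*config.dwell_hr) * 60)
        p = ports[cur_port]
        lat_parts.append(np.full(dwell, p.lat))
        lon_parts.append(np.full(dwell, p.lon))
        state_parts.append(np.full(dwell, "dock"))
        track = VesselTrack(vessel_id, t0_vessel,
                            np.concatenate(lat_parts),
                            np.concatenate(lon_parts),
                            np.concatenate(state_parts))
        tracks[vessel_id] = track
        rec_frames.append(sample_vms(track, config.sampling, rng))

    truth = _truth_frame(truth_rows)
    records = pd.concat(rec_frames, ignore_index=True)
    observer = emit_observer_records(truth, config.observer_coverage,
                                     config.clock_error, rng)
    tickets = emit_fish_tickets(truth, tracks, areas, config.ticket_errors, rng)
    calendar = [(t.vessel_id, t.true_start, t.true_end)
                for t in truth.itertuples() if t.behavior == "tender"
                and rng.random() < config.tender_calendar_coverage]
    return FleetData(ports=ports, stat_areas=areas, fishing_areas=fishing_areas,
                     truth=truth, tracks=tracks, records=records,
                     observer=observer, tickets=tickets,
                     tender_calendar=calendar)
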