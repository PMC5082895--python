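"""Trip duration and distance, observer comparison, and bias correction.

Record-to-record sums understate a trip because the boundary records sit
some distance from the dock.  For ordinary ports the trajectory is
linearly extrapolated to zero distance from port; the two large hub
ports (whose 10-nmi buffers hide substantial in-port transit) instead
receive mean in-port travel constants estimated from trips with
contiguous coverage between dock and threshold.

The duration measurement error of a trip bounded by records at interval
Delta is at most 2*Delta - 2 minutes (up to Delta - 1 at each end), which
grows with the largest transmission gap in the trip; estimated durations
are validated against observer dock-to-dock durations under that bound.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from . import geo
from .synthetic_fleet import PortSet

log = logging.getLogger(__name__)

_EPS_MIN = 1e-6  # float tolerance on the bound comparison
SPEED_FLOOR_KN = 0.5


@dataclass(frozen=True)
class InPortConstants:
    """Mean within-buffer travel for a hub port (outbound and inbound)."""

    port_id: str
    start_nmi: float
    start_min: float
    end_nmi: float
    end_min: float


def registry_constants(ports: PortSet) -> dict:
    """In-port constants declared in the port registry, keyed by port id."""
    out = {}
    for p in ports:
        if p.inport_constants:
            out[p.port_id] = InPortConstants(p.port_id, *p.inport_constants)
    return out


def measurement_error_bound(max_interval_min) -> float:
    """Maximum duration measurement error: 2 * interval - 2 minutes."""
    iv = float(max_interval_min)
    if iv < 1:
        raise ValueError("transmission interval must be >= 1 min")
    return 2.0 * iv - 2.0


def duration_where_bound_is_pct(bound_min, pct: float = 5.0) -> float:
    """Trip duration at which ``bound_min`` equals ``pct`` percent of it."""
    if pct <= 0:
        raise ValueError("pct must be positive")
    return float(bound_min) / (pct / 100.0)


def extrapolate_to_port(dist_nmi, adjacent_speed_kn,
                        floor_kn: float = SPEED_FLOOR_KN):
    """Linear extrapolation of a trip boundary to 0 nmi from port.

    Returns (added_nmi, added_min).  The adjacent-segment speed is
    floored to avoid unbounded added time on near-stationary boundaries.
    """
    d = float(dist_nmi)
    v = adjacent_speed_kn
    if v is None or not np.isfinite(v) or v < floor_kn:
        v = floor_kn
    return d, d / v * 60.0


def compute_trip_metrics(trips, records: pd.DataFrame, ports: PortSet,
                         constants: dict | None = None):
    """Fill duration/distance (plus adjusted start/end times) on each trip.

    duration = (last - first record time) + boundary adjustments;
    distance = sum of great-circle legs + boundary adjustments.  The hub
    constants path applies only when the boundary record lies at or
    beyond the port radius (the in-port travel was unobserved); a
    boundary record inside the radius is extrapolated like any other.
    Trips with an unknown port at either end are flagged as lower bounds.
    """
    if constants is None:
        constants = registry_constants(ports)
    lat = records["lat"].to_numpy()
    lon = records["lon"].to_numpy()
    speed = records["speed_kn"].to_numpy(dtype=float)
    dist_port = records["dist_port_nmi"].to_numpy(dtype=float)
    for trip in trips:
        pos = trip.record_index
        la, lo = lat[pos], lon[pos]
        base_nmi = geo.polyline_nmi(la, lo)
        base_min = (trip.last_record_time
                    - trip.first_record_time).total_seconds() / 60.0
        trip.duration_lower_bound = False
        for side in ("start", "end"):
            port_id = trip.start_port if side == "start" else trip.end_port
            add_nmi = add_min = 0.0
            if port_id is None:
                trip.duration_lower_bound = True
            else:
                bpos = pos[0] if side == "start" else pos[-1]
                d = dist_port[bpos]
                radius = ports[port_id].radius_nmi if port_id in ports else 0.0
                c = constants.get(port_id)
                if c is not None and d >= radius - 1e-9:
                    add_nmi, add_min = ((c.start_nmi, c.start_min)
                                        if side == "start"
                                        else (c.end_nmi, c.end_min))
                else:
                    v = speed[pos[1]] if side == "start" and len(pos) > 1 \
                        else speed[bpos]
                    add_nmi, add_min = extrapolate_to_port(d, v)
            if side == "start":
                trip.start_add_nmi, trip.start_add_min = add_nmi, add_min
            else:
                trip.end_add_nmi, trip.end_add_min = add_nmi, add_min
        trip.distance_nmi = base_nmi + trip.start_add_nmi + trip.end_add_nmi
        trip.duration_min = base_min + trip.start_add_min + trip.end_add_min
        trip.start_time = trip.first_record_time \
            - pd.Timedelta(minutes=trip.start_add_min)
        trip.end_time = trip.last_record_time \
            + pd.Timedelta(minutes=trip.end_add_min)
    return trips


def trip_duration(trip, records, ports, constants=None) -> float:
    """Duration in minutes of a single trip (boundaries resolved)."""
    compute_trip_metrics([trip], records, ports, constants)
    return trip.duration_min


def trip_distance(trip, records, ports, constants=None) -> float:
    """Distance in nmi of a single trip (boundaries resolved)."""
    compute_trip_metrics([trip], records, ports, constants)
    return trip.distance_nmi


# ---------------------------------------------------------------------------
# In-port constants estimation
# ---------------------------------------------------------------------------

def estimate_inport_constants(records: pd.DataFrame, trips, port_id,
                              ports: PortSet,
                              max_interval_min: float = 30.0) -> InPortConstants:
    """Estimate mean within-buffer travel for a hub from contiguous trips.

    Qualifying traversals have every transmission interval at most
    ``max_interval_min`` between the dock and the radius threshold.  The
    threshold crossing is linearly interpolated on distance-from-port and
    the dock departure/arrival is back-extrapolated from the first/last
    moving record, so the estimate is unbiased by the sampling phase.
    With zero qualifying traversals the port registry defaults are
    retained with a warning.
    """
    radius = ports[port_id].radius_nmi
    ts = records["timestamp"].to_numpy()
    speed = records["speed_kn"].to_numpy(dtype=float)
    dist = records["dist_port_nmi"].to_numpy(dtype=float)
    in_port = records["in_port"].to_numpy()
    cand = records["port_candidate"].to_numpy()
    vid = records["vessel_id"].to_numpy()
    prev_d = records["dist_prev_nmi"].to_numpy(dtype=float)

    starts, ends = [], []
    for trip in trips:
        if trip.start_port == port_id and not trip.start_port_inferred:
            res = _traversal(trip.record_index[0], -1, port_id, radius, ts,
                             speed, dist, in_port, cand, vid, prev_d,
                             max_interval_min)
            if res:
                starts.append(res)
        if trip.end_port == port_id and not trip.end_port_inferred:
            res = _traversal(trip.record_index[-1], +1, port_id, radius, ts,
                             speed, dist, in_port, cand, vid, prev_d,
                             max_interval_min)
            if res:
                ends.append(res)
    if not starts or not ends:
        warnings.warn(f"no qualifying traversals for port {port_id!r}; "
                      "registry defaults retained", stacklevel=2)
        c = ports[port_id].inport_constants
        if c is None:
            raise ValueError(f"port {port_id!r} has no default constants")
        return InPortConstants(port_id, *c)
    s_nmi = float(np.mean([d for d, _ in starts]))
    s_min = float(np.mean([m for _, m in starts]))
    e_nmi = float(np.mean([d for d, _ in ends]))
    e_min = float(np.mean([m for _, m in ends]))
    return InPortConstants(port_id, s_nmi, s_min, e_nmi, e_min)


def _traversal(boundary_pos, direction, port_id, radius, ts, speed, dist,
               in_port, cand, vid, prev_d, max_iv):
    """One dock<->threshold traversal (distance_nmi, duration_min) or None.

    ``direction`` -1 walks backward from a trip's first record (outbound
    traversal), +1 forward from its last record (inbound).
    """
    # collect the adjacent in-port run at this port
    run = []
    j = boundary_pos + direction
    while (0 <= j < len(ts) and in_port[j] and cand[j] == port_id
           and vid[j] == vid[boundary_pos]):
        run.append(j)
        j += direction
    if not run:
        return None
    seq = run[::-1] + [boundary_pos] if direction == -1 \
        else [boundary_pos] + run  # time-ordered dock->sea or sea->dock
    # keep only the segment between the dock dwell and the threshold:
    # the run also contains the dwell and the other traversal of the visit.
    # a record at the dock is "docked" even when its segment-average speed
    # is nonzero (the vessel arrived or departed mid-segment)
    def _docked(k):
        return (dist[k] <= 0.2 or not np.isfinite(speed[k])
                or speed[k] <= SPEED_FLOOR_KN)

    docked = [i for i, k in enumerate(seq) if k != boundary_pos and _docked(k)]
    if not docked:
        return None
    seq = seq[docked[-1]:] if direction == -1 else seq[:docked[0] + 1]
    if len(seq) < 3:  # dock anchor, >= 1 moving record, boundary
        return None
    iv = np.abs(np.diff(ts[seq]) / np.timedelta64(1, "m"))
    if (iv > max_iv + 1e-9).any():
        return None
    moving = [k for k in seq if k != boundary_pos and not _docked(k)]
    if not moving:
        return None
    if direction == -1:  # outbound: dock, moving ..., boundary(at sea)
        m = moving[0]
        v_ref = speed[seq[seq.index(m) + 1]]  # next-segment speed, fully moving
        if not np.isfinite(v_ref) or v_ref <= 0:
            return None
        t_depart = ts[m] - np.timedelta64(int(dist[m] / v_ref * 3600), "s")
        l_in, l_b = seq[-2], seq[-1]
    else:  # inbound: boundary(at sea), ... moving, dock
        m = moving[-1]
        v_ref = speed[m]  # arrival-segment speed
        if not np.isfinite(v_ref) or v_ref <= 0:
            return None
        t_depart = ts[m] + np.timedelta64(int(dist[m] / v_ref * 3600), "s")
        l_in, l_b = seq[1], seq[0]
    # threshold crossing interpolated on distance-from-port; boundary
    # records inside the radius (corridor-vetoed approaches) do not span
    # the threshold and cannot anchor the interpolation
    d0, d1 = dist[l_in], dist[l_b]
    if d1 < radius or d1 <= d0:
        return None
    f = (radius - d0) / (d1 - d0)
    t_cross = ts[l_in] + f * (ts[l_b] - ts[l_in])
    dur = abs((t_cross - t_depart) / np.timedelta64(1, "m"))
    # path length: extrapolated dock leg + recorded legs + partial leg
    if direction == -1:
        between = seq[seq.index(m):seq.index(l_in) + 1]
    else:
        between = seq[seq.index(l_in):seq.index(m) + 1]
    d_path = dist[m]
    for a, b in zip(between[:-1], between[1:]):
        d_path += prev_d[max(a, b)]
    d_path += f * prev_d[max(l_in, l_b)]
    return float(d_path), float(dur)


# ---------------------------------------------------------------------------
# Observer comparison
# ---------------------------------------------------------------------------

def compare_with_observer(trips, observer: pd.DataFrame,
                          records: pd.DataFrame,
                          min_obs_duration: float = 200.0):
    """Per-trip duration comparison against observer dock-to-dock records.

    A trip matches an observer trip when at least one of its records
    falls inside the observed window; observer trips of at most
    ``min_obs_duration`` minutes are excluded (by construction such trips
    never left port).  Positive percent error means over-estimation.

    Returns ``(comparisons, summary)``; the summary reports the share of
    trips within their measurement-error bound, the share within 5%
    error, the union of the two, the Spearman rank correlation, and the
    aggregate (summed-duration) error.
    """
    if "observed_trip_id" not in records.columns:
        raise ValueError("records lack observer matching; run match_observer")
    obs_by_id = {o.obs_trip_id: o for o in observer.itertuples()}
    obs_col = records["observed_trip_id"].to_numpy()
    rows = []
    for trip in trips:
        ids, counts = np.unique(
            [o for o in obs_col[trip.record_index] if o is not None],
            return_counts=True)
        if len(ids) == 0 or trip.duration_min is None:
            continue
        o = obs_by_id[ids[np.argmax(counts)]]
        obs_min = (o.obs_end - o.obs_start).total_seconds() / 60.0
        if obs_min <= min_obs_duration:
            continue
        trip.observed_trip_id = o.obs_trip_id
        bound = measurement_error_bound(max(trip.max_gap_min, 1.0))
        diff = trip.duration_min - obs_min
        rows.append({
            "trip_id": trip.trip_id, "obs_trip_id": o.obs_trip_id,
            "est_duration_min": trip.duration_min,
            "obs_duration_min": obs_min, "diff_min": diff,
            "pct_error": diff / obs_min * 100.0,
            "error_bound_min": bound,
            "within_bound": abs(diff) <= bound + _EPS_MIN,
        })
    comparisons = pd.DataFrame(rows)
    if comparisons.empty:
        return comparisons, {}
    est = comparisons["est_duration_min"].to_numpy()
    obs = comparisons["obs_duration_min"].to_numpy()
    within = comparisons["within_bound"].to_numpy()
    le5 = np.abs(comparisons["pct_error"].to_numpy()) <= 5.0
    rho = scipy.stats.spearmanr(est, obs).statistic if len(est) > 1 else np.nan
    summary = {
        "n_pairs": int(len(comparisons)),
        "share_within_bound": float(within.mean()),
        "share_pct_le_5": float(le5.mean()),
        "share_within_or_le_5": float((within | le5).mean()),
        "spearman_rho": float(rho),
        "aggregate_pct_error": float((est.sum() - obs.sum()) / obs.sum() * 100.0),
        "mean_abs_pct_error": float(np.abs(comparisons["pct_error"]).mean()),
    }
    return comparisons, summary


# ---------------------------------------------------------------------------
# Bias-correction regression
# ---------------------------------------------------------------------------

@dataclass
class BiasCorrection:
    """Piecewise log-linear correction of estimated durations.

    ``params`` maps segment name ('below'/'above') to (intercept, slope)
    of ln(observed) ~ ln(estimated); identity segments carry (0, 1).
    """

    breakpoint_min: float
    params: dict
    corrected: np.ndarray
    summary: dict

    def predict(self, est_duration_min):
        est = np.asarray(est_duration_min, dtype=float)
        out = np.empty_like(est)
        for name, mask in (("below", est < self.breakpoint_min),
                           ("above", est >= self.breakpoint_min)):
            a, b = self.params[name]
            out[mask] = np.exp(a + b * np.log(est[mask]))
        return out


def bias_correction_regression(comparisons: pd.DataFrame,
                               breakpoint_min: float = 700.0,
                               min_pairs: int = 50) -> BiasCorrection:
    """Fit a piecewise log-linear bias correction around a duration cutoff.

    Observed duration is regressed on estimated duration (both on the log
    scale) separately below and above the breakpoint, reflecting the
    bimodal short-transit / multi-day-fishing duration structure.
    Degenerate segments (too few pairs, or constant estimates) fall back
    to the identity with a warning.  Pre/post errors are reported so the
    caller can accept or reject the correction.
    """
    if len(comparisons) < min_pairs:
        raise ValueError(f"need >= {min_pairs} comparison pairs, "
                         f"got {len(comparisons)}")
    est = comparisons["est_duration_min"].to_numpy(dtype=float)
    obs = comparisons["obs_duration_min"].to_numpy(dtype=float)
    params = {}
    for name, mask in (("below", est < breakpoint_min),
                       ("above", est >= breakpoint_min)):
        x = np.log(est[mask])
        y = np.log(obs[mask])
        if mask.sum() < 10 or np.ptp(x) < 1e-9:
            warnings.warn(f"degenerate design in segment {name!r}; identity "
                          "correction used", stacklevel=2)
            params[name] = (0.0, 1.0)
            continue
        res = sm.OLS(y, sm.add_constant(x)).fit()
        params[name] = (float(res.params[0]), float(res.params[1]))
    bc = BiasCorrection(breakpoint_min, params, np.empty(0), {})
    corrected = bc.predict(est)
    bc.corrected = corrected

    def _errs(e):
        return {"aggregate_pct_error": float((e.sum() - obs.sum())
                                             / obs.sum() * 100.0),
                "mean_abs_pct_error": float(np.mean(np.abs(e - obs)
                                                    / obs * 100.0))}

    bc.summary = {"pre": _errs(est), "post": _errs(corrected),
                  "params": params}
    return bc
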