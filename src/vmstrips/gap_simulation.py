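"""Monte-Carlo simulation of distance underestimation from VMS gaps.

Removing records from a trip straightens (and so shortens) its polyline:
with straight-line distances between fixes, every gap can only reduce
the estimated distance traveled (triangle inequality), and the loss
grows with path sinuosity.  The experiment removes 1-4 consecutive
records from trips with regular transmission (every interval 25-35 min),
simulating single gaps of 60, 90, 120 and 150 min, and summarizes the
per-draw percent reduction in over-water path length relative to the
complete trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo


def select_complete_trips(trips, records: pd.DataFrame,
                          interval_range=(25.0, 35.0), min_records: int = 6):
    """Trips whose every transmission interval lies within the range.

    ``min_records`` keeps trips long enough to remove four consecutive
    records while leaving a fix on each side.
    """
    ts = records["timestamp"].to_numpy()
    lo, hi = interval_range
    out = []
    for t in trips:
        if t.n_records < min_records:
            continue
        iv = np.diff(ts[t.record_index]) / np.timedelta64(1, "m")
        if ((iv >= lo) & (iv <= hi)).all():
            out.append(t)
    return out


def remove_records(n_records: int, k: int, position: int) -> np.ndarray:
    """Keep-mask after removing ``k`` consecutive records.

    ``position`` indexes the first-removed record; for k > 1 the
    additional removals take the records immediately prior, so the block
    removed is ``[position - k + 1, position]``.  At least one record
    must remain on each side of the gap.
    """
    if not 1 <= k <= 4:
        raise ValueError("k must be in 1..4")
    if position - k + 1 < 1 or position > n_records - 2:
        raise ValueError(
            f"position {position} leaves no flanking record for k={k}")
    keep = np.ones(n_records, dtype=bool)
    keep[position - k + 1:position + 1] = False
    return keep


def degraded_distance_nmi(lats, lons, keep: np.ndarray) -> float:
    """Polyline length through the kept records only."""
    return geo.polyline_nmi(np.asarray(lats)[keep], np.asarray(lons)[keep])


def _floor_tiny(x: float) -> float:
    """Clamp float-epsilon negatives (collinear paths) to exactly zero."""
    return 0.0 if -1e-8 < x < 0.0 else x


def pct_reduction(lats, lons, keep: np.ndarray) -> float:
    """Percent reduction of path length caused by the removal.

    Nonnegative by the triangle inequality; exact zero on collinear paths.
    """
    full = geo.polyline_nmi(lats, lons)
    if full <= 0:
        return 0.0
    return _floor_tiny((full - degraded_distance_nmi(lats, lons, keep))
                       / full * 100.0)


@dataclass
class GapSimResult:
    """Summary of the percent-reduction distribution for one gap size."""

    k_removed: int
    gap_min: float
    pct: np.ndarray
    mean: float
    mad: float          # mean absolute deviation from the mean
    quartiles: tuple    # (q1, median, q3)
    n_outliers: int     # draws > 1.5 x upper quartile
    n_draws: int


def _summarize(k, gap_min, pct):
    pct = np.asarray(pct)
    q1, q2, q3 = np.percentile(pct, [25, 50, 75])
    return GapSimResult(
        k_removed=k, gap_min=gap_min, pct=pct,
        mean=float(pct.mean()),
        mad=float(np.abs(pct - pct.mean()).mean()),
        quartiles=(float(q1), float(q2), float(q3)),
        n_outliers=int((pct > 1.5 * q3).sum()),
        n_draws=len(pct))


def run_bias_experiment(trips, records: pd.DataFrame, n_draws: int = 5000,
                        k_set=(1, 2, 3, 4), rng=None,
                        nominal_interval_min: float = 30.0):
    """Record-removal experiment over regularly-sampled trips.

    Per draw: a trip is sampled with replacement, a gap position is
    sampled uniformly (valid for the largest k), and the percent path
    reduction is computed for each k in ``k_set`` by extending the same
    gap backward.  Distances are over-water polyline lengths only (port
    constants are gap-invariant).  Also returns the ECDF of the maximum
    transmission gap of the *input* trips and a tidy per-draw table.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if not trips:
        raise ValueError("no eligible trips")
    kmax = max(k_set)
    lat = records["lat"].to_numpy()
    lon = records["lon"].to_numpy()
    # precompute per-trip leg lengths and cumulative sums: removing the
    # block [p-k+1, p] replaces legs (p-k, ..., p+1) with a single chord
    legs, coords, totals = [], [], []
    for t in trips:
        la, lo = lat[t.record_index], lon[t.record_index]
        leg = geo.haversine_nmi(la[:-1], lo[:-1], la[1:], lo[1:])
        legs.append(np.concatenate([[0.0], np.cumsum(leg)]))
        coords.append((la, lo))
        totals.append(float(leg.sum()))
    draws = {k: np.empty(n_draws) for k in k_set}
    table = []
    ti = rng.integers(0, len(trips), n_draws)
    for d in range(n_draws):
        i = int(ti[d])
        n = trips[i].n_records
        p = int(rng.integers(kmax, n - 1))  # first-removed index
        la, lo = coords[i]
        cum = legs[i]
        for k in k_set:
            a, b = p - k, p + 1  # flanking kept records
            removed_len = cum[b] - cum[a]
            chord = float(geo.haversine_nmi(la[a], lo[a], la[b], lo[b]))
            red = _floor_tiny((removed_len - chord) / totals[i] * 100.0)
            draws[k][d] = red
            table.append({"draw": d, "trip_id": trips[i].trip_id, "k": k,
                          "gap_min": (k + 1) * nominal_interval_min,
                          "pct_reduction": red})
    results = {k: _summarize(k, (k + 1) * nominal_interval_min, draws[k])
               for k in k_set}
    max_gaps = np.sort([t.max_gap_min for t in trips])
    ecdf = pd.DataFrame({"max_gap_min": max_gaps,
                         "ecdf": np.arange(1, len(max_gaps) + 1) / len(max_gaps)})
    return results, pd.DataFrame(table), ecdf


def exhaustive_mean_reduction(lats, lons, k: int) -> float:
    """Exact mean percent reduction over all valid gap positions.

    Independent enumeration oracle for small fixtures: averages
    ``pct_reduction`` over every position valid for the *largest* k of
    the experiment (4), matching the experiment's position distribution.
    """
    n = len(lats)
    positions = range(4, n - 1)
    vals = [pct_reduction(lats, lons, remove_records(n, k, p))
            for p in positions]
    return float(np.mean(vals))
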