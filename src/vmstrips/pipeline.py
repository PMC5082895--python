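"""End-to-end orchestration: simulate -> preprocess -> segment -> match ->
metrics -> classify -> gap simulation, with auditable per-stage counts.

Missing or corrupted records are pervasive in VMS work, so every filter
logs how many records or trips it consumed and produced; the run summary
records those counts alongside the scientific outputs (trips by season x
year x type, the observer-comparison summary and the gap-bias summary).
Runs are deterministic given the configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from . import synthetic_fleet as sf
from . import ticket_matching as tm
from . import trip_classification as tc
from . import trip_metrics as tmx
from . import trip_segmentation as seg
from . import vms_preprocess as pre
from .gap_simulation import run_bias_experiment, select_complete_trips

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for a full run (YAML-loadable).

    When ``simulate`` is set the inputs are generated synthetically;
    otherwise the ``vms/ports/areas/observer/tickets`` paths are read.
    """

    seed: int = 0
    simulate: dict | None = field(default_factory=dict)
    vms: str | None = None
    ports: str | None = None
    areas: str | None = None
    observer: str | None = None
    tickets: str | None = None
    gapsim_draws: int = 2000
    classify: bool = True
    use_corridor: bool = True

    @classmethod
    def from_yaml(cls, path):
        cfg = cls(**(yaml.safe_load(Path(path).read_text()) or {}))
        for name in ("vms", "ports", "areas", "observer", "tickets"):
            p = getattr(cfg, name)
            if cfg.simulate is None and p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {name!r}: no such file {p}")
        return cfg


def truth_accounting(trips, truth: pd.DataFrame) -> dict:
    """Account for every truth trip: recovered one-to-one, split, or missed.

    A truth trip is *recovered* when exactly one detected trip overlaps
    it in time, *split* when several do, *missed* when none does.
    Detected trips overlapping several truth trips are *merged*.
    """
    spans = {}
    for t in trips:
        spans.setdefault(t.vessel_id, []).append(
            (t.first_record_time, t.last_record_time, t.trip_id))
    recovered = split = missed = 0
    hits_per_trip = {}
    for tr in truth.itertuples():
        n = 0
        for a, b, tid in spans.get(tr.vessel_id, []):
            if b > tr.true_start and a < tr.true_end:
                n += 1
                hits_per_trip[tid] = hits_per_trip.get(tid, 0) + 1
        recovered += n == 1
        split += n > 1
        missed += n == 0
    merged = sum(1 for v in hits_per_trip.values() if v > 1)
    return {"truth_trips": int(len(truth)), "recovered_one_to_one": recovered,
            "split": split, "missed": missed, "merged_detected": merged}


def _season_year_table(trips) -> pd.DataFrame:
    """Trips by season x year x type (percent per type within each row)."""
    rows = []
    for t in trips:
        rows.append({"season": tm.season_of(t.first_record_time),
                     "year": t.first_record_time.year, "label": t.label})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    tab = (df.groupby(["season", "year", "label"]).size()
           .unstack(fill_value=0))
    tab["total_trips"] = tab.sum(axis=1)
    for c in ("afa_fishing", "other_fishing", "nonfishing", "unclassified"):
        if c in tab.columns:
            tab[f"pct_{c}"] = (tab[c] / tab["total_trips"] * 100).round(1)
    return tab.reset_index()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages; writes artifacts to ``out_dir``, returns summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    counts = {}

    if config.simulate is not None:
        fc = sf.FleetConfig.from_dict(config.simulate)
        fleet = sf.simulate_fleet(fc, rng)
        ports, areas = fleet.ports, fleet.stat_areas
        records, observer, tickets = fleet.records, fleet.observer, fleet.tickets
        fleet.truth.to_csv(out / "truth.csv", index=False)
        counts["truth_trips"] = len(fleet.truth)
    else:
        for name in ("vms", "ports", "areas", "observer", "tickets"):
            if getattr(config, name) is None:
                raise ValueError(f"config must set {name!r} when not simulating")
        ports = vio.read_ports(config.ports)
        areas = vio.read_stat_areas_geojson(config.areas)
        records = vio.read_vms_csv(config.vms)
        observer = vio.read_observer_csv(config.observer)
        tickets = vio.read_tickets_csv(config.tickets)
        fleet = None

    vio.write_vms_csv(records, out / "vms_raw.csv")
    vio.write_ports_csv(ports, out / "ports.csv")
    counts["records_raw"] = len(records)

    # preprocess
    records = pre.deduplicate(records)
    counts["records_deduplicated"] = len(records)
    records = pre.derive_fields(records, ports, areas)
    records = pre.filter_speed(records)
    counts["records_speed_filtered"] = len(records)
    records = pre.match_observer(records, observer)

    # segment
    rules = seg.PortRuleSet()
    if config.use_corridor and "dutch_harbor" in ports and "akutan" in ports:
        rules.corridors = [seg.dutch_akutan_corridor(ports)]
    records = seg.assign_port_status(records, ports, rules)
    trips = seg.segment_trips(records, ports, rules)
    counts["trips_segmented"] = len(trips)
    trips = seg.prune_short_trips(trips)
    counts["trips_after_pruning"] = len(trips)

    # metrics with estimated hub constants
    constants = {}
    base = tmx.registry_constants(ports)
    tmx.compute_trip_metrics(trips, records, ports, base)
    for pid in base:
        try:
            constants[pid] = tmx.estimate_inport_constants(
                records, trips, pid, ports)
        except ValueError:
            constants[pid] = base[pid]
    tmx.compute_trip_metrics(trips, records, ports, constants)

    # ticket matching + ports backfill
    matches = tm.match_tickets(trips, tickets, records)
    counts["ticket_matches"] = len(matches)
    tickets_by_id = {t.ticket_id: {"port": t.port,
                                   "landing_date": t.landing_date}
                     for t in tickets.itertuples()}
    for trip in trips:
        if trip.end_port is None and trip.ticket_ids:
            last = records.iloc[trip.record_index[-1]]
            tm.backfill_ports(trip, tickets_by_id[trip.ticket_ids[0]],
                              ({"lat": last["lat"], "lon": last["lon"],
                                "timestamp": last["timestamp"]}, None), ports)
    tmx.compute_trip_metrics(trips, records, ports, constants)

    # observer comparison
    comparisons, comp_summary = tmx.compare_with_observer(
        trips, observer, records)
    comparisons.to_csv(out / "observer_comparison.csv", index=False)

    # classification
    clf_report = {}
    if config.classify:
        rule_cfg = tc.RuleConfig(
            corridors=[p for p, _ in rules.corridors],
            nonfishing_calendar=(fleet.tender_calendar if fleet else []))
        _, clf_report = tc.classify_trips(
            trips, records, ports, rule_cfg,
            fishing_areas=(fleet.fishing_areas if fleet else None),
            seed=config.seed)
        pollock = set(fleet.fishing_areas) if fleet else set()
        tm.partition_afa([t for t in trips if t.label == "fishing"],
                         tickets, records, tm.AfaConfig(pollock_areas=pollock))

    # gap simulation
    eligible = select_complete_trips(trips, records)
    gap_summary = {}
    if eligible:
        results, table, ecdf = run_bias_experiment(
            eligible, records, n_draws=config.gapsim_draws,
            rng=np.random.default_rng(config.seed + 1))
        table.to_csv(out / "gapsim_draws.csv", index=False)
        ecdf.to_csv(out / "max_gap_ecdf.csv", index=False)
        gap_summary = {str(k): {"gap_min": r.gap_min, "mean_pct": r.mean,
                                "mad_pct": r.mad, "quartiles": r.quartiles,
                                "n_outliers": r.n_outliers}
                       for k, r in results.items()}
    counts["gapsim_eligible_trips"] = len(eligible)

    seg.trips_to_frame(trips).to_csv(out / "trips.csv", index=False)
    season_table = _season_year_table(trips)
    season_table.to_csv(out / "trips_by_season_year.csv", index=False)

    summary = {
        "seed": config.seed,
        "counts": counts,
        "truth_accounting": (truth_accounting(trips, fleet.truth)
                             if fleet is not None else None),
        "observer_comparison": comp_summary,
        "classification": clf_report,
        "gap_bias": gap_summary,
        "inport_constants": {p: vars(c) for p, c in constants.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True, default=str))
    return summary
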