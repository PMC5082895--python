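"""Shared fixtures: processed synthetic fleets at several study conditions.

Fleets are generated once per session; all expensive pipeline stages
(preprocess, segmentation, metrics) are run here so individual tests stay
fast.  Seeds are fixed so every run sees identical data.
"""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from vmstrips import (synthetic_fleet as sf, ticket_matching as tm,
                      trip_metrics as tmx, trip_segmentation as seg,
                      vms_preprocess as pre)


@dataclass
class ProcessedFleet:
    fleet: sf.FleetData
    records: pd.DataFrame
    rules: seg.PortRuleSet
    trips: list
    constants: dict


def process_fleet(config: sf.FleetConfig, seed: int) -> ProcessedFleet:
    """Run the standard chain simulate -> preprocess -> segment -> metrics."""
    fleet = sf.simulate_fleet(config, np.random.default_rng(seed))
    rec = pre.deduplicate(fleet.records)
    rec = pre.derive_fields(rec, fleet.ports, fleet.stat_areas)
    rec = pre.filter_speed(rec)
    rec = pre.match_observer(rec, fleet.observer)
    rules = seg.PortRuleSet(corridors=[seg.dutch_akutan_corridor(fleet.ports)])
    rec = seg.assign_port_status(rec, fleet.ports, rules)
    trips = seg.prune_short_trips(seg.segment_trips(rec, fleet.ports, rules))
    base = tmx.registry_constants(fleet.ports)
    tmx.compute_trip_metrics(trips, rec, fleet.ports, base)
    constants = {pid: tmx.estimate_inport_constants(rec, trips, pid, fleet.ports)
                 for pid in base}
    tmx.compute_trip_metrics(trips, rec, fleet.ports, constants)
    tm.match_tickets(trips, fleet.tickets, rec)
    return ProcessedFleet(fleet, rec, rules, trips, constants)


NO_NOISE = sf.SamplingModel(jitter_fraction_35_60=0.0, long_gap_fraction=0.0)


@pytest.fixture(scope="session")
def toy_ports():
    return sf.build_port_registry("bering_toy")


@pytest.fixture(scope="session")
def small_fleet():
    """No-noise fleet: exact 30-min sampling, full observer coverage."""
    cfg = sf.FleetConfig(n_vessels=6, trips_per_vessel=6, sampling=NO_NOISE)
    return process_fleet(cfg, seed=123)


@pytest.fixture(scope="session")
def classifier_fleet():
    """800-trip fleet with dropped tickets so some fishing trips reach
    the model; sized to give the model a few hundred training trips."""
    cfg = sf.FleetConfig(n_vessels=40, trips_per_vessel=20,
                         ticket_errors=sf.TicketErrorModel(p_drop=0.1))
    return process_fleet(cfg, seed=5)


def one_to_one_recovery(trips, truth: pd.DataFrame) -> float:
    """Share of truth trips overlapped by exactly one detected trip."""
    spans = {}
    for t in trips:
        spans.setdefault(t.vessel_id, []).append(
            (t.first_record_time, t.last_record_time))
    ok = 0
    for tr in truth.itertuples():
        n = sum(1 for a, b in spans.get(tr.vessel_id, [])
                if b > tr.true_start and a < tr.true_end)
        ok += n == 1
    return ok / len(truth)


def truth_behavior_of(trip, truth: pd.DataFrame):
    """Behavior of the truth trip with the largest time overlap, or None."""
    best, best_ov = None, 0.0
    for tr in truth.itertuples():
        if tr.vessel_id != trip.vessel_id:
            continue
        ov = (min(trip.last_record_time, tr.true_end)
              - max(trip.first_record_time, tr.true_start)).total_seconds()
        if ov > best_ov:
            best, best_ov = tr.behavior, ov
    return best
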