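"""The synthetic fleet generator honors its own contracts."""

import numpy as np
import pandas as pd
import pytest

from vmstrips import geo
from vmstrips import synthetic_fleet as sf

T0 = pd.Timestamp("2013-02-01 00:00")


class TestPortRegistry:
    def test_bering_toy_preset(self):
        """The toy layout has 5 ports, two hubs with in-port constants."""
        ports = sf.build_port_registry("bering_toy")
        assert len(ports) == 5
        hubs = [p for p in ports if p.radius_nmi == 10.0]
        assert len(hubs) == 2
        assert all(p.inport_constants is not None for p in hubs)
        assert all(p.radius_nmi < 10 for p in ports
                   if p.inport_constants is None)

    def test_overlapping_buffers_warn(self):
        a = sf.PortSpec("a", 54.0, -166.0, 10.0)
        lab, lob = geo.destination(54.0, -166.0, 90.0, 3.0)
        b = sf.PortSpec("b", float(lab), float(lob), 10.0)
        with pytest.warns(UserWarning, match="overlap"):
            sf.PortSet([a, b])

    @pytest.mark.parametrize("bad", [
        [sf.PortSpec("a", 54, -166, 5)],                      # too few
        [sf.PortSpec("a", 54, -166, 5)] * 2,                  # duplicate id
    ])
    def test_invalid_registries_raise(self, bad):
        with pytest.raises(ValueError):
            sf.PortSet(bad)

    def test_invalid_coordinates_and_radius_raise(self):
        with pytest.raises(ValueError):
            sf.PortSpec("x", 95.0, 0.0, 5.0)
        with pytest.raises(ValueError):
            sf.PortSpec("x", 54.0, -166.0, 12.0)

    def test_nearest_at_port_coordinates_is_identity(self, toy_ports):
        p = toy_ports["kodiak"]
        ids, d = toy_ports.nearest(p.lat, p.lon)
        assert ids[0] == "kodiak"
        assert d[0] == pytest.approx(0.0, abs=1e-9)

    def test_csv_roundtrip(self, toy_ports, tmp_path):
        path = tmp_path / "ports.csv"
        toy_ports.to_frame().to_csv(path, index=False)
        back = sf.PortSet.from_frame(pd.read_csv(path))
        assert set(back.ids) == set(toy_ports.ids)
        assert back["akutan"].inport_constants == \
            toy_ports["akutan"].inport_constants


class TestSimulateTrip:
    def test_transit_distance_is_speed_times_time(self):
        """A straight 10-kn transit between ports 120 nmi apart takes ~12 h."""
        la2, lo2 = geo.destination(55.0, -165.0, 80.0, 120.0)
        ports = sf.PortSet([sf.PortSpec("a", 55.0, -165.0, 3.0),
                            sf.PortSpec("b", float(la2), float(lo2), 3.0)])
        plan = sf.TripPlan("transit", "a", "b", T0, duration_hr=13,
                           speed_kn=10.0)
        truth, (la, lo, st) = sf.simulate_trip("V", plan, ports,
                                               np.random.default_rng(0))
        assert truth.true_distance_nmi == pytest.approx(120.0, rel=0.01)
        hours = (truth.true_end - truth.true_start).total_seconds() / 3600
        assert hours == pytest.approx(12.0, rel=0.01)

    def test_transit_unreachable_raises(self):
        la2, lo2 = geo.destination(55.0, -165.0, 80.0, 120.0)
        ports = sf.PortSet([sf.PortSpec("a", 55.0, -165.0, 3.0),
                            sf.PortSpec("b", float(la2), float(lo2), 3.0)])
        plan = sf.TripPlan("transit", "a", "b", T0, duration_hr=2.0)
        with pytest.raises(ValueError, match="unreachable"):
            sf.simulate_trip("V", plan, ports, np.random.default_rng(0))

    def test_fishing_trip_has_slow_legs_and_closes_at_docks(self, toy_ports):
        plan = sf.TripPlan("afa_fishing", "dutch_harbor", "dutch_harbor",
                           T0, duration_hr=48)
        truth, (la, lo, st) = sf.simulate_trip("V", plan, toy_ports,
                                               np.random.default_rng(1))
        p = toy_ports["dutch_harbor"]
        assert (la[0], lo[0]) == (p.lat, p.lon)
        assert la[-1] == pytest.approx(p.lat, abs=1e-6)
        # per-minute speeds during fishing legs sit in the 0-5 kn band
        fish = np.flatnonzero(st == "fishing")
        assert fish.size > 60
        steps = geo.haversine_nmi(la[fish[:-1]], lo[fish[:-1]],
                                  la[fish[:-1] + 1], lo[fish[:-1] + 1]) * 60
        # small slack for the tangent-plane distortion of wander bouts
        assert (steps <= 5.0 * 1.1).all()
        assert np.median(steps) < 5.0
        assert truth.true_distance_nmi == pytest.approx(
            geo.polyline_nmi(la, lo))

    def test_same_seed_same_track(self, toy_ports):
        plan = sf.TripPlan("other_fishing", "kodiak", "kodiak", T0,
                           duration_hr=30)
        t1, (la1, lo1, _) = sf.simulate_trip("V", plan, toy_ports,
                                             np.random.default_rng(7))
        t2, (la2, lo2, _) = sf.simulate_trip("V", plan, toy_ports,
                                             np.random.default_rng(7))
        assert np.array_equal(la1, la2) and np.array_equal(lo1, lo2)
        assert t1.true_distance_nmi == t2.true_distance_nmi


def _track(toy_ports, minutes=6000, seed=2):
    plan = sf.TripPlan("afa_fishing", "dutch_harbor", "dutch_harbor",
                       T0, duration_hr=minutes / 60)
    truth, (la, lo, st) = sf.simulate_trip("V", plan, toy_ports,
                                           np.random.default_rng(seed))
    return truth, sf.VesselTrack("V", T0, la, lo, st)


class TestSampleVms:
    def test_no_noise_intervals_exactly_nominal(self, toy_ports):
        _, track = _track(toy_ports)
        model = sf.SamplingModel(jitter_fraction_35_60=0, long_gap_fraction=0)
        rec = sf.sample_vms(track, model, np.random.default_rng(0))
        iv = rec["timestamp"].diff().dropna().dt.total_seconds() / 60
        assert (iv == 30.0).all()

    def test_degenerate_all_gaps(self, toy_ports):
        _, track = _track(toy_ports)
        model = sf.SamplingModel(long_gap_fraction=1.0,
                                 jitter_fraction_35_60=0.0,
                                 gap_lengths_min=(240,), gap_weights=(1.0,))
        rec = sf.sample_vms(track, model, np.random.default_rng(0))
        iv = rec["timestamp"].diff().dropna().dt.total_seconds() / 60
        assert (iv == 240.0).all()

    def test_interval_fractions_within_binomial_error(self):
        """Observed jitter/gap fractions agree with a binomial oracle."""
        n_min = 10_000 * 32  # enough track for ~10,000 intervals
        track = sf.VesselTrack("V", T0, np.full(n_min, 55.0),
                               np.full(n_min, -165.0),
                               np.full(n_min, "dock"))
        # gap mixture excluding 60 min so jittered (35-60 min) and gapped
        # intervals are distinguishable in the emitted stream
        model = sf.SamplingModel(gap_lengths_min=(90, 120, 150, 240, 480),
                                 gap_weights=(0.3, 0.25, 0.2, 0.15, 0.1))
        rec = sf.sample_vms(track, model, np.random.default_rng(3))
        iv = rec["timestamp"].diff().dropna().dt.total_seconds() / 60
        n = len(iv)
        assert n > 5000
        for frac, obs in [(model.jitter_fraction_35_60,
                           ((iv >= 35) & (iv <= 60)).mean()),
                          (model.long_gap_fraction, (iv > 60).mean())]:
            se = np.sqrt(frac * (1 - frac) / n)
            assert abs(obs - frac) <= 3 * se

    def test_records_lie_on_track_and_shorten_path(self, toy_ports):
        truth, track = _track(toy_ports)
        rec = sf.sample_vms(track, sf.SamplingModel(),
                            np.random.default_rng(4))
        mins = ((rec["timestamp"] - T0).dt.total_seconds() // 60).astype(int)
        assert np.array_equal(rec["lat"].to_numpy(), track.lat[mins])
        assert geo.polyline_nmi(rec["lat"], rec["lon"]) \
            <= truth.true_distance_nmi + 1e-9

    def test_invalid_fractions_raise(self):
        with pytest.raises(ValueError):
            sf.SamplingModel(jitter_fraction_35_60=0.8, long_gap_fraction=0.3)
        with pytest.raises(ValueError):
            sf.SamplingModel(long_gap_fraction=-0.1)


def _toy_truth():
    return pd.DataFrame([{
        "vessel_id": "V0", "trip_index": 0, "behavior": "afa_fishing",
        "true_start": T0, "true_end": T0 + pd.Timedelta(minutes=3000),
        "start_port": "dutch_harbor", "end_port": "dutch_harbor",
        "true_distance_nmi": 150.0,
        "fishing_start": T0 + pd.Timedelta(minutes=300)}])


class TestObserverEmission:
    def test_full_coverage_zero_error_is_exact(self):
        obs = sf.emit_observer_records(_toy_truth(), 1.0, None,
                                       np.random.default_rng(0))
        assert len(obs) == 1
        assert obs.loc[0, "obs_start"] == T0

    def test_zero_coverage_is_empty(self):
        obs = sf.emit_observer_records(_toy_truth(), 0.0, None,
                                       np.random.default_rng(0))
        assert obs.empty

    def test_late_start_mode_shortens_observed_duration(self):
        ce = sf.ClockErrorModel(p_late_start=1.0, late_start_min=120)
        obs = sf.emit_observer_records(_toy_truth(), 1.0, ce,
                                       np.random.default_rng(0))
        dur = (obs.loc[0, "obs_end"] - obs.loc[0, "obs_start"])
        assert dur == pd.Timedelta(minutes=3000 - 120)

    def test_invalid_coverage_raises(self):
        with pytest.raises(ValueError):
            sf.emit_observer_records(_toy_truth(), 1.5, None,
                                     np.random.default_rng(0))


class TestTicketEmission:
    @pytest.fixture(scope="class")
    def fleet(self):
        cfg = sf.FleetConfig(n_vessels=3, trips_per_vessel=4)
        return sf.simulate_fleet(cfg, np.random.default_rng(11))

    def test_only_fishing_trips_get_tickets(self, fleet):
        fishing = fleet.truth["behavior"].isin(
            ["afa_fishing", "other_fishing"])
        assert len(fleet.tickets) == int(fishing.sum())
        assert set(fleet.tickets["truth_index"]) == \
            set(np.flatnonzero(fishing))

    def test_ticket_port_and_landing_date_match_truth(self, fleet):
        for tk in fleet.tickets.itertuples():
            tr = fleet.truth.iloc[tk.truth_index]
            assert tk.port == tr["end_port"]
            assert tk.landing_date == pd.Timestamp(tr["true_end"].date())
            assert tk.fishing_start_date <= tk.landing_date
            assert len(tk.stat_areas) >= 1

    def test_date_swap_mode_inverts_window(self):
        cfg = sf.FleetConfig(n_vessels=3, trips_per_vessel=4,
                             ticket_errors=sf.TicketErrorModel(p_date_swap=1.0))
        fleet = sf.simulate_fleet(cfg, np.random.default_rng(11))
        multiday = fleet.tickets["landing_date"] != \
            fleet.tickets["fishing_start_date"]
        assert (fleet.tickets.loc[multiday, "landing_date"]
                < fleet.tickets.loc[multiday, "fishing_start_date"]).all()
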