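"""Trip duration/distance, in-port constants, observer comparison, bias fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmstrips import geo
from vmstrips import trip_metrics as tmx
from vmstrips import trip_segmentation as seg
from vmstrips import vms_preprocess as pre

from .test_preprocess import make_records, radial_points

T0 = pd.Timestamp("2013-02-01 00:00")


class TestMeasurementErrorBound:
    @pytest.mark.parametrize("interval,bound", [(30, 58), (1, 0), (60, 118)])
    def test_bound_formula(self, interval, bound):
        assert tmx.measurement_error_bound(interval) == bound

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            tmx.measurement_error_bound(0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(iv=st.floats(1, 1e4))
    def test_exact_identity(self, iv):
        """bound(d) - 2*d + 2 == 0 for every interval."""
        assert tmx.measurement_error_bound(iv) - 2 * iv + 2 == \
            pytest.approx(0, abs=1e-9)

    def test_five_percent_duration_threshold(self):
        """A 58-min error is 5% of a 1,160-min trip."""
        assert tmx.duration_where_bound_is_pct(58.0, 5.0) == \
            pytest.approx(1160.0)


class TestExtrapolateToPort:
    def test_zero_distance_is_identity(self):
        assert tmx.extrapolate_to_port(0.0, 4.0) == (0.0, 0.0)

    def test_two_nmi_at_four_knots_adds_half_hour(self):
        assert tmx.extrapolate_to_port(2.0, 4.0) == (2.0, 30.0)

    def test_speed_floor_caps_added_time(self):
        d, m = tmx.extrapolate_to_port(1.0, 0.1)
        assert m == pytest.approx(1.0 / 0.5 * 60.0)

    def test_missing_speed_uses_floor(self):
        _, m = tmx.extrapolate_to_port(1.0, np.nan)
        assert m == pytest.approx(120.0)


def _manual_trip(records, start_port, end_port):
    return seg.Trip(trip_id="t0", vessel_id="V0",
                    record_index=np.arange(len(records)),
                    start_port=start_port, end_port=end_port,
                    first_record_time=records["timestamp"].iloc[0],
                    last_record_time=records["timestamp"].iloc[-1],
                    n_records=len(records),
                    max_gap_min=float(records["timestamp"].diff()
                                      .dt.total_seconds().div(60).max()))


class TestTripMetrics:
    def test_hub_to_hub_duration_and_distance_add_constants(self, toy_ports):
        """Records spanning 1,000 min over a 100-nmi path, both boundaries
        outside the Dutch Harbor buffer: + 80+80 min and + 10+10 nmi."""
        p = toy_ports["dutch_harbor"]
        # out and back along one bearing, staying beyond the 10-nmi radius
        dists = np.concatenate([np.linspace(10.5, 50, 10),
                                np.linspace(50, 10.5, 10)])
        pts = radial_points(p.lat, p.lon, 135.0, dists)
        rec = make_records(pts, interval_min=1000 / 19)
        rec = pre.derive_fields(rec, toy_ports)
        trip = _manual_trip(rec, "dutch_harbor", "dutch_harbor")
        path = geo.polyline_nmi(rec["lat"], rec["lon"])
        tmx.compute_trip_metrics([trip], rec, toy_ports)
        assert trip.duration_min == pytest.approx(1000 + 80 + 80, abs=1e-6)
        assert trip.distance_nmi == pytest.approx(path + 10 + 10, abs=1e-9)

    def test_small_port_boundary_extrapolates_to_zero(self, toy_ports):
        """Boundary 2 nmi out at 4 kn: +2 nmi, +30 min at each end."""
        p = toy_ports["sand_point"]
        pts = radial_points(p.lat, p.lon, 90.0, [2, 4, 6, 4, 2])
        rec = pre.derive_fields(make_records(pts), toy_ports)
        trip = _manual_trip(rec, "sand_point", "sand_point")
        tmx.compute_trip_metrics([trip], rec, toy_ports)
        assert trip.start_add_nmi == pytest.approx(2.0, rel=1e-6)
        assert trip.start_add_min == pytest.approx(30.0, rel=1e-6)
        assert trip.end_add_min == pytest.approx(30.0, rel=1e-6)

    def test_unknown_port_flags_lower_bound(self, toy_ports):
        pts = radial_points(56.5, -158.0, 45.0, [20, 25, 30])
        rec = pre.derive_fields(make_records(pts), toy_ports)
        trip = _manual_trip(rec, None, None)
        tmx.compute_trip_metrics([trip], rec, toy_ports)
        assert trip.duration_lower_bound
        assert trip.duration_min == pytest.approx(60.0)
        assert trip.distance_nmi == pytest.approx(10.0, rel=1e-6)

    def test_adding_records_never_decreases_distance(self, small_fleet):
        """Monotonicity: dropping interior records only shortens a trip."""
        rec = small_fleet.records
        for trip in small_fleet.trips[:20]:
            pos = trip.record_index
            full = geo.polyline_nmi(rec["lat"].to_numpy()[pos],
                                    rec["lon"].to_numpy()[pos])
            sub = geo.polyline_nmi(rec["lat"].to_numpy()[pos[::2]],
                                   rec["lon"].to_numpy()[pos[::2]])
            assert sub <= full + 1e-9

    def test_synthetic_distance_within_two_percent_of_truth(
            self, small_fleet):
        """No-gap sampled trip distance tracks the 1-min truth closely."""
        fleet = small_fleet.fleet
        ratios = []
        for trip in small_fleet.trips:
            best, ov = None, 0
            for tr in fleet.truth.itertuples():
                if tr.vessel_id != trip.vessel_id:
                    continue
                o = (min(trip.last_record_time, tr.true_end)
                     - max(trip.first_record_time, tr.true_start)
                     ).total_seconds()
                if o > ov:
                    best, ov = tr, o
            if best is None:
                continue
            ratios.append(trip.distance_nmi / best.true_distance_nmi)
        # discretization makes the estimate a slight underestimate
        assert np.median(ratios) == pytest.approx(1.0, abs=0.05)
        assert np.mean(np.abs(np.array(ratios) - 1.0) < 0.10) > 0.9


class TestEstimateInportConstants:
    def _approach_records(self, toy_ports, speed_kn=8.0, dwell=4,
                          interval=30):
        """Outbound and inbound traversals of the Dutch buffer at a fixed
        speed, with dock dwells on both sides of the excursion."""
        p = toy_ports["dutch_harbor"]
        step = speed_kn * interval / 60.0
        out_d = list(np.arange(step, 45.0, step))
        dists = [0.0] * dwell + out_d + out_d[::-1] + [0.0] * dwell
        pts = radial_points(p.lat, p.lon, 200.0, dists)
        return make_records(pts, interval_min=interval)

    def _segmented(self, toy_ports, rec):
        rules = seg.PortRuleSet()
        rec = seg.assign_port_status(pre.derive_fields(rec, toy_ports),
                                     toy_ports, rules)
        trips = seg.segment_trips(rec, toy_ports, rules)
        return rec, trips

    def test_known_eight_knot_approach_recovers_75_minutes(self, toy_ports):
        """10 nmi at 8 kn is 75 min: the estimator recovers it exactly."""
        rec, trips = self._segmented(
            toy_ports, self._approach_records(toy_ports))
        c = tmx.estimate_inport_constants(rec, trips, "dutch_harbor",
                                          toy_ports)
        assert c.start_min == pytest.approx(75.0, abs=1.0)
        assert c.end_min == pytest.approx(75.0, abs=1.0)
        assert c.start_nmi == pytest.approx(10.0, abs=0.1)

    def test_slow_transmission_traversals_excluded(self, toy_ports):
        """45-min intervals disqualify the traversal: defaults retained."""
        rec, trips = self._segmented(
            toy_ports, self._approach_records(toy_ports, interval=45))
        with pytest.warns(UserWarning, match="defaults"):
            c = tmx.estimate_inport_constants(rec, trips, "dutch_harbor",
                                              toy_ports)
        assert (c.start_nmi, c.start_min) == (10.0, 80.0)

    def test_no_traversals_returns_registry_defaults(self, toy_ports):
        rec = pre.derive_fields(
            make_records([(56.5, -158.0)] * 3), toy_ports)
        rec = seg.assign_port_status(rec, toy_ports, seg.PortRuleSet())
        with pytest.warns(UserWarning):
            c = tmx.estimate_inport_constants(rec, [], "akutan", toy_ports)
        assert (c.start_nmi, c.start_min, c.end_nmi, c.end_min) == \
            (13.0, 101.0, 12.0, 92.0)


class TestCompareWithObserver:
    def test_exact_match_has_zero_diff(self, small_fleet):
        comp, summary = tmx.compare_with_observer(
            small_fleet.trips, small_fleet.fleet.observer,
            small_fleet.records)
        assert summary["n_pairs"] > 20
        assert summary["share_within_bound"] == 1.0
        assert summary["spearman_rho"] > 0.99

    def test_short_observed_trips_excluded(self, small_fleet):
        comp, _ = tmx.compare_with_observer(
            small_fleet.trips, small_fleet.fleet.observer,
            small_fleet.records, min_obs_duration=1e9)
        assert comp.empty


class TestBiasCorrection:
    def _pairs(self, n=400, bias_below=1.0, seed=0):
        rng = np.random.default_rng(seed)
        obs = np.exp(rng.uniform(np.log(250), np.log(8000), n))
        est = np.where(obs < 700, obs * bias_below, obs)
        est *= np.exp(rng.normal(0, 0.01, n))
        return pd.DataFrame({"est_duration_min": est,
                             "obs_duration_min": obs})

    def test_unbiased_pairs_give_identity_fit(self):
        bc = tmx.bias_correction_regression(self._pairs())
        for a, b in bc.params.values():
            assert a == pytest.approx(0.0, abs=0.05)
            assert b == pytest.approx(1.0, abs=0.02)

    def test_injected_bias_below_breakpoint_recovered(self):
        """A +10% over-estimate below 700 min is corrected away."""
        comp = self._pairs(bias_below=1.10, seed=1)
        bc = tmx.bias_correction_regression(comp)
        short = comp["est_duration_min"] < 700
        pre_err = np.abs(comp.loc[short, "est_duration_min"]
                         - comp.loc[short, "obs_duration_min"]).mean()
        post_err = np.abs(bc.corrected[short.to_numpy()]
                          - comp.loc[short, "obs_duration_min"]).mean()
        assert post_err < 0.3 * pre_err
        assert bc.summary["post"]["mean_abs_pct_error"] < \
            bc.summary["pre"]["mean_abs_pct_error"]

    def test_constant_estimates_fall_back_to_identity(self):
        comp = pd.DataFrame({"est_duration_min": np.full(100, 500.0),
                             "obs_duration_min": np.linspace(300, 900, 100)})
        with pytest.warns(UserWarning, match="degenerate"):
            bc = tmx.bias_correction_regression(comp)
        assert bc.params["below"] == (0.0, 1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="50"):
            tmx.bias_correction_regression(self._pairs(n=10))
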