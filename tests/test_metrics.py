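import math

import pytest

from vaxchain.engine import (
    ReplicationResult,
    RouteTrip,
    ScenarioConfig,
    SimulationResults,
    run_simulation,
)
from vaxchain.metrics import (
    aggregate,
    histogram,
    storage_utilization,
    transport_utilization,
    vaccine_availability,
)


class TestAvailability:
    def test_published_operand_pair(self):
        # 58,482 of 583,575 opportunities missed -> 90%
        assert vaccine_availability(583_575 - 58_482, 583_575) == pytest.approx(
            0.8998, abs=5e-4
        )

    def test_nobody_served(self):
        assert vaccine_availability(0, 10) == 0.0

    def test_everyone_served(self):
        assert vaccine_availability(7, 7) == 1.0

    def test_no_arrivals_is_missing(self):
        assert math.isnan(vaccine_availability(0, 0))

    def test_received_above_arrivals_is_inconsistent(self):
        with pytest.raises(ValueError):
            vaccine_availability(5, 4)


class TestTransportUtilization:
    def test_double_booked_vehicle(self):
        dr, actual = transport_utilization(200.0, 100.0, 100.0)
        assert (dr, actual) == (2.0, 1.0)

    def test_empty_trip(self):
        assert transport_utilization(0.0, 0.0, 50.0) == (0.0, 0.0)

    def test_exact_fit(self):
        assert transport_utilization(50.0, 50.0, 50.0) == (1.0, 1.0)

    def test_zero_capacity_rejected(self):
        with pytest.raises(ValueError):
            transport_utilization(1.0, 1.0, 0.0)


class TestStorageUtilization:
    @pytest.mark.parametrize(
        "stored,cap,expected", [(50, 100, 0.5), (0, 10, 0.0), (10, 10, 1.0)]
    )
    def test_ratio(self, stored, cap, expected):
        assert storage_utilization(stored, cap) == expected

    def test_storage_less_store_is_missing(self):
        assert math.isnan(storage_utilization(0.0, 0.0))


def _fake_results(utils):
    """One replication with one trip per route at the given
    demand-requested utilizations (capacity 100)."""
    trips = [
        RouteTrip(f"district-clinic-D1-C{i}", 10, 100.0 * u, min(100.0 * u, 100.0), 100.0)
        for i, u in enumerate(utils)
    ]
    rep = ReplicationResult(
        replication=0, clinic_stats={}, route_trips=trips, storage={}, ledgers={}
    )
    return SimulationResults(config=ScenarioConfig(replications=1), replications=[rep])


class TestAggregation:
    def test_single_value_summary_is_the_value(self):
        tables = aggregate(_fake_results([0.4]))
        row = tables["transport_summary"]
        dr = row[row.metric == "demand_requested_utilization"].iloc[0]
        assert dr["median"] == dr["min"] == dr["max"] == pytest.approx(0.4)

    def test_median_of_two_routes(self):
        tables = aggregate(_fake_results([0.4, 0.6]))
        dr = tables["transport_summary"]
        dr = dr[dr.metric == "demand_requested_utilization"].iloc[0]
        assert dr["median"] == pytest.approx(0.5)

    def test_median_and_range_with_overfill(self):
        tables = aggregate(_fake_results([0.82, 1.50, 3.22]))
        dr = tables["transport_summary"]
        dr = dr[dr.metric == "demand_requested_utilization"].iloc[0]
        assert dr["median"] == pytest.approx(1.50)
        assert (dr["min"], dr["max"]) == (pytest.approx(0.82), pytest.approx(3.22))

    def test_histogram_has_open_top_bin(self):
        h = histogram([0.05, 0.15, 1.5, 2.5])
        assert h.iloc[-1]["bin"] == ">100%"
        assert h.iloc[-1]["count"] == 2


class TestAccountingInvariants:
    def test_arrivals_partition_exactly(self, mini_network, mini_demand, catalog):
        """administered + missed = arrivals per antigen per replication."""
        res = run_simulation(
            mini_network, catalog, mini_demand, ScenarioConfig(replications=2, seed=6)
        )
        for rep in res.replications:
            totals = {}
            for (clinic, antigen), st in rep.clinic_stats.items():
                t = totals.setdefault(antigen, [0, 0, 0])
                t[0] += st.arrivals
                t[1] += st.administered
                t[2] += st.missed
            for antigen, (arr, adm, miss) in totals.items():
                assert adm + miss == arr
                # ledger agrees with the per-clinic accumulators
                assert rep.ledgers[antigen].administered == adm
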