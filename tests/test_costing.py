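import math

import pytest

from vaxchain.catalog import MissingCostError, substitute_presentation
from vaxchain.costing import (
    administration_cost,
    cost_per_injection,
    disposal_cost,
    scenario_cost,
    wasted_dose_cost,
)
from vaxchain.engine import ScenarioConfig, run_simulation


class TestAdministrationCost:
    def test_full_ten_dose_vial(self, catalog, cost_inputs):
        # 10 x (0.246 + 0.07) + 1 x 0.06
        m = catalog.active_presentation("M")
        assert administration_cost(10, 1, cost_inputs, m) == pytest.approx(3.22)

    def test_zero_doses_cost_nothing(self, catalog, cost_inputs):
        m = catalog.active_presentation("M")
        assert administration_cost(0, 0, cost_inputs, m) == 0.0

    def test_single_dose_vial(self, catalog, cost_inputs):
        # 0.943 + 0.07 + 0.06
        m1 = substitute_presentation(catalog, "M", 1).active_presentation("M")
        assert administration_cost(1, 1, cost_inputs, m1) == pytest.approx(1.073)

    def test_oral_vaccine_needs_no_syringe(self, catalog, cost_inputs):
        opv = catalog.active_presentation("OPV")
        opv = type(opv)(**{**opv.__dict__, "price_per_dose": 0.10})
        # liquid + oral: no reconstitution, no injection syringe
        assert administration_cost(20, 1, cost_inputs, opv) == pytest.approx(2.0)

    def test_unknown_price_fails_loudly(self, catalog, cost_inputs):
        m2 = catalog.get("M", 2)
        with pytest.raises(MissingCostError):
            administration_cost(1, 1, cost_inputs, m2)


class TestWastedDoseCost:
    def test_no_waste_costs_nothing(self):
        assert wasted_dose_cost(0, 0.246) == 0.0

    def test_product(self):
        assert wasted_dose_cost(100, 0.246) == pytest.approx(24.60)

    def test_unknown_price_fails(self):
        with pytest.raises(MissingCostError):
            wasted_dose_cost(5, None)


class TestDisposalCost:
    def test_one_vial_with_syringes(self, cost_inputs):
        # mass = 3.522 + 6.625 + 10 x 6.625 = 76.397 g at 0.0069 USD/g
        with pytest.warns(UserWarning):  # safety box cost unset -> 0
            cost = disposal_cost({10: 1}, 1, 10, 10, cost_inputs)
        assert cost == pytest.approx(0.527, abs=5e-4)

    def test_no_waste_stream(self, cost_inputs):
        with pytest.warns(UserWarning):
            assert disposal_cost({}, 0, 0, 0, cost_inputs) == 0.0

    def test_per_kg_rate_equivalent(self, cost_inputs):
        mass = 76.397
        per_g = cost_inputs.waste_disposal_cost_per_g * mass
        per_kg = cost_inputs.waste_disposal_cost_per_kg * mass / 1000.0
        assert per_g == pytest.approx(per_kg)


class TestCostPerInjection:
    def test_published_ten_dose_figures(self):
        assert round(cost_per_injection(244_759, 583_575 - 58_482), 2) == 0.47

    def test_published_single_dose_figures(self):
        assert round(cost_per_injection(586_214, 583_264 - 117_167), 2) == 1.26

    def test_one_dose_identity(self):
        assert cost_per_injection(3.5, 1) == 3.5

    def test_zero_administered_is_missing(self):
        assert math.isnan(cost_per_injection(10.0, 0))


class TestScenarioCost:
    def test_single_dose_total_is_admin_plus_disposal(
        self, mini_network, mini_demand, catalog, cost_inputs
    ):
        cat1 = substitute_presentation(catalog, "M", 1)
        res = run_simulation(
            mini_network,
            cat1,
            mini_demand,
            ScenarioConfig(measles_doses_per_vial=1, replications=2, seed=13),
        )
        with pytest.warns(UserWarning):
            b = scenario_cost(res, cat1, cost_inputs)
        assert b.wasted_dose_cost == 0.0
        assert b.total == pytest.approx(b.administration_cost + b.disposal_cost)
        assert b.cost_per_injection == pytest.approx(
            b.total / b.doses_administered
        )

    def test_breakdown_additivity(
        self, mini_network, mini_demand, catalog, cost_inputs
    ):
        res = run_simulation(
            mini_network, catalog, mini_demand,
            ScenarioConfig(replications=2, seed=13),
        )
        with pytest.warns(UserWarning):
            b = scenario_cost(res, catalog, cost_inputs)
        assert b.total == pytest.approx(
            b.administration_cost + b.wasted_dose_cost + b.disposal_cost
        )
        assert b.wasted_dose_cost > 0  # 10-dose vials do waste doses
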