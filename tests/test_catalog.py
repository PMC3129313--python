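import math

import pytest

from vaxchain.catalog import (
    CatalogSchemaError,
    MissingCostError,
    PresentationLookupError,
    adjust_cost_year,
    load_vaccine_catalog,
    save_vaccine_catalog,
    substitute_presentation,
)


class TestBundledCatalog:
    def test_measles_baseline_row(self, catalog):
        m = catalog.active_presentation("M")
        assert m.doses_per_vial == 10
        assert m.packed_volume_per_dose == 2.6
        assert m.diluent_volume_per_dose == 0.5
        assert m.formulation == "lyophilized"

    def test_only_opv_is_frozen(self, catalog):
        for p in catalog.active_presentations():
            expected = "freezer" if p.antigen_id == "OPV" else "refrigerator"
            assert p.storage_class == expected

    def test_measles_volume_rises_as_vial_shrinks(self, catalog):
        vols = [
            catalog.get("M", d).packed_volume_per_dose for d in (10, 5, 2, 1)
        ]
        assert vols == sorted(vols) and len(set(vols)) == 4

    def test_formulation_split_matches_open_vial_rule(self, catalog):
        # lyophilized vaccines have no 28-day keep; liquid ones do
        for p in catalog.active_presentations():
            if p.formulation == "liquid":
                assert p.open_vial_lifetime_days == 28
            else:
                assert p.open_vial_lifetime_days is None

    def test_two_dose_measles_price_is_explicitly_missing(self, catalog):
        p = catalog.get("M", 2)
        assert p.price_per_dose is None
        with pytest.raises(MissingCostError):
            p.require_price()


class TestLoading:
    def test_round_trip(self, catalog, tmp_path):
        path = tmp_path / "cat.csv"
        save_vaccine_catalog(catalog, path)
        again = load_vaccine_catalog(path)
        assert again.presentations == catalog.presentations
        assert again.active == catalog.active

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("antigen_id,doses_per_vial\nM,10\n")
        with pytest.raises(CatalogSchemaError, match="schedule"):
            load_vaccine_catalog(path)

    def test_empty_file_is_schema_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(CatalogSchemaError):
            load_vaccine_catalog(path)


class TestSubstitution:
    @pytest.mark.parametrize("size,price", [(5, 0.450), (1, 0.943)])
    def test_switches_active_measles(self, catalog, size, price):
        new = substitute_presentation(catalog, "M", size)
        m = new.active_presentation("M")
        assert m.doses_per_vial == size
        assert m.price_per_dose == price
        # everything else untouched
        for a in new.antigens():
            if a != "M":
                assert new.active[a] == catalog.active[a]

    def test_one_dose_volume(self, catalog):
        new = substitute_presentation(catalog, "M", 1)
        assert new.active_presentation("M").packed_volume_per_dose == 26.1

    def test_identity_substitution(self, catalog):
        same = substitute_presentation(catalog, "M", 10)
        assert same.active == catalog.active

    def test_idempotent_and_invertible(self, catalog):
        once = substitute_presentation(catalog, "M", 5)
        twice = substitute_presentation(once, "M", 5)
        assert once.active == twice.active
        back = substitute_presentation(once, "M", 10)
        assert back.active == catalog.active

    def test_absent_presentation_is_lookup_error(self, catalog):
        with pytest.raises(PresentationLookupError):
            substitute_presentation(catalog, "M", 3)


class TestCostYearAdjustment:
    @pytest.mark.parametrize(
        "amount,y0,y1,rate,expected",
        [
            (100, 2011, 2011, 0.03, 100.0),
            (100, 2010, 2011, 0.03, 103.0),
            (100, 2004, 2010, 0.03, 119.41),  # 100 * 1.03**6
        ],
    )
    def test_compounding(self, amount, y0, y1, rate, expected):
        assert round(adjust_cost_year(amount, y0, y1, rate), 2) == expected

    def test_deflation_inverts_inflation(self):
        up = adjust_cost_year(100, 2004, 2010, 0.03)
        assert adjust_cost_year(up, 2010, 2004, 0.03) == pytest.approx(100)


class TestCostInputs:
    def test_table_values(self, cost_inputs):
        assert cost_inputs.price_per_dose[10] == 0.246
        assert cost_inputs.price_per_dose[2] is None
        assert cost_inputs.empty_vial_mass_g[10] == 3.522
        assert cost_inputs.waste_disposal_cost_per_g == 0.0069

    def test_per_kg_and_per_g_rates_consistent(self, cost_inputs):
        assert cost_inputs.waste_disposal_cost_per_g == pytest.approx(
            6.850 / 1000, abs=1e-4
        )

    def test_unknown_vial_mass_raises(self, cost_inputs):
        with pytest.raises(MissingCostError):
            cost_inputs.require_vial_mass(2)

    def test_unset_safety_box_warns_and_defaults_zero(self, cost_inputs):
        with pytest.warns(UserWarning):
            assert cost_inputs.effective_safety_box_cost() == 0.0
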