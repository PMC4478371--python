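import numpy as np
import pandas as pd
import pytest
import yaml

from ceamodel.cea_frontier import FrontierEntry
from ceamodel.cohort_engine import CEAResult
from ceamodel.inputs_io import (
    DistributionSpec,
    ScenarioValidationError,
    bundled_scenario_path,
    load_scenario,
    parse_scenario,
    read_curve_csv,
    save_scenario,
    scenario_to_dict,
    write_curve_csv,
    write_results,
)
from ceamodel.sensitivity import CEACCurve

# Every nonzero adverse-event probability of the base-case input table,
# keyed (strategy, event, grade band).
AE_PROBS = {
    ("vemurafenib", "vomiting_nausea", "g12"): 0.0023,
    ("vemurafenib", "vomiting_nausea", "g34"): 0.0010,
    ("vemurafenib", "diarrhea", "g12"): 0.0230,
    ("vemurafenib", "diarrhea", "g34"): 0.0005,
    ("vemurafenib", "hyperkeratosis", "g12"): 0.0172,
    ("vemurafenib", "hyperkeratosis", "g34"): 0.0010,
    ("vemurafenib", "skin_papilloma", "g12"): 0.0169,
    ("vemurafenib", "squamous_cell_carcinoma", "g34"): 0.0105,
    ("vemurafenib", "keratoacanthoma", "g12"): 0.0051,
    ("vemurafenib", "neutropenia", "g12"): 0.0002,
    ("vemurafenib", "neutropenia", "g34"): 0.0002,
    ("dabrafenib", "vomiting_nausea", "g12"): 0.0009,
    ("dabrafenib", "hyperkeratosis", "g12"): 0.0113,
    ("dabrafenib", "hyperkeratosis", "g34"): 0.0009,
    ("dabrafenib", "squamous_cell_carcinoma", "g12"): 0.0018,
    ("dabrafenib", "squamous_cell_carcinoma", "g34"): 0.0036,
    ("dabrafenib", "neutropenia", "g34"): 0.0004,
    ("dabrafenib", "palmar_plantar_erythrodysesthesia", "g12"): 0.0055,
    ("dabrafenib", "palmar_plantar_erythrodysesthesia", "g34"): 0.0018,
    ("dacarbazine", "vomiting_nausea", "g12"): 0.0106,
    ("dacarbazine", "vomiting_nausea", "g34"): 0.0007,
    ("dacarbazine", "diarrhea", "g12"): 0.0006,
    ("dacarbazine", "diarrhea", "g34"): 0.0001,
    ("dacarbazine", "neutropenia", "g12"): 0.0019,
    ("dacarbazine", "neutropenia", "g34"): 0.0086,
    ("dacarbazine", "leukopenia", "g12"): 0.0013,
    ("dacarbazine", "leukopenia", "g34"): 0.0007,
    ("dacarbazine", "thrombocytopenia", "g34"): 0.0020,
}

# (base, low, high) of each nonzero management-cost entry.
AE_COSTS = {
    ("vemurafenib", "vomiting_nausea", "g12"): (274.58, 274.58, 419.54),
    ("vemurafenib", "vomiting_nausea", "g34"): (6855.76, 4480.05, 8009.39),
    ("vemurafenib", "diarrhea", "g12"): (5.81, 5.81, 45.89),
    ("vemurafenib", "diarrhea", "g34"): (7404.11, 3550.28, 7845.00),
    ("vemurafenib", "hyperkeratosis", "g12"): (126.66, 114.26, 424.95),
    ("vemurafenib", "hyperkeratosis", "g34"): (1082.84, 1070.84, 1706.93),
    ("vemurafenib", "skin_papilloma", "g12"): (73.00, 61.00, 97.00),
    ("vemurafenib", "squamous_cell_carcinoma", "g34"): (1595.00, 1128.00, 3408.00),
    ("vemurafenib", "keratoacanthoma", "g12"): (113.67, 66.72, 181.31),
    ("dabrafenib", "vomiting_nausea", "g12"): (274.58, 274.58, 419.54),
    ("dabrafenib", "hyperkeratosis", "g12"): (126.66, 114.26, 424.95),
    ("dabrafenib", "hyperkeratosis", "g34"): (1082.84, 1070.84, 1706.93),
    ("dabrafenib", "squamous_cell_carcinoma", "g12"): (1595.00, 1128.00, 3408.00),
    ("dabrafenib", "squamous_cell_carcinoma", "g34"): (1595.00, 1128.00, 3408.00),
    ("dabrafenib", "palmar_plantar_erythrodysesthesia", "g12"): (113.67, 113.67, 178.62),
    ("dabrafenib", "palmar_plantar_erythrodysesthesia", "g34"): (113.67, 113.67, 178.62),
    ("dacarbazine", "vomiting_nausea", "g12"): (84.66, 2.78, 4485.98),
    ("dacarbazine", "vomiting_nausea", "g34"): (6665.84, 4208.25, 12075.84),
    ("dacarbazine", "diarrhea", "g12"): (5.81, 5.81, 45.89),
    ("dacarbazine", "diarrhea", "g34"): (7404.11, 3550.28, 7845.00),
}

DRUG_COSTS = {
    "dacarbazine": (988.86, 678.29, 1356.85),
    "dabrafenib": (7569.60, 5677.20, 9462.00),
    "vemurafenib": (10807.40, 8105.55, 13509.25),
}

UTILITIES = {
    "dacarbazine": (0.69, 0.45),
    "dabrafenib": (0.79, 0.52),
    "vemurafenib": (0.73, 0.49),
}


def minimal_doc(**overrides):
    doc = {
        "schema_version": 1,
        "strategies": [
            {
                "name": "a",
                "monthly_drug_cost": {"base": 100.0, "family": "gamma"},
                "utility_stable": {"base": 0.8, "family": "beta"},
                "utility_progression": {"base": 0.5, "family": "beta"},
            }
        ],
        "survival": {
            "a": {
                "os": {"exponential": {"median_months": 6, "follow_up_months": 8}},
                "pfs": {"exponential": {"median_months": 3, "follow_up_months": 8}},
            }
        },
    }
    doc.update(overrides)
    return doc


class TestDistributionSpec:
    def test_order_invariant(self):
        with pytest.raises(ScenarioValidationError, match="low <= base <= high"):
            DistributionSpec(base=0.5, low=0.6, high=0.7, family="beta")

    def test_beta_bounds(self):
        with pytest.raises(ScenarioValidationError, match="beta"):
            DistributionSpec(base=1.1, low=0.0, high=1.2, family="beta")

    def test_gamma_nonnegative(self):
        with pytest.raises(ScenarioValidationError, match="gamma"):
            DistributionSpec(base=1.0, low=-0.5, high=2.0, family="gamma")

    def test_fixed_degenerate_allowed(self):
        spec = DistributionSpec.fixed(5.0)
        assert spec.is_degenerate

    def test_unknown_family(self):
        with pytest.raises(ScenarioValidationError, match="family"):
            DistributionSpec(base=1.0, low=1.0, high=1.0, family="normal")


class TestBundledFixture:
    def test_three_strategies(self, fixture_scenario):
        assert fixture_scenario.strategy_names == [
            "dacarbazine",
            "dabrafenib",
            "vemurafenib",
        ]

    @pytest.mark.parametrize("name", list(DRUG_COSTS))
    def test_drug_costs(self, fixture_scenario, name):
        spec = fixture_scenario.strategy(name).monthly_drug_cost
        assert (spec.base, spec.low, spec.high) == DRUG_COSTS[name]
        assert spec.family == "gamma"

    @pytest.mark.parametrize("name", list(UTILITIES))
    def test_utilities_with_verbatim_unit_ranges(self, fixture_scenario, name):
        s = fixture_scenario.strategy(name)
        u_stable, u_prog = UTILITIES[name]
        assert s.utility_stable.base == u_stable
        assert s.utility_progression.base == u_prog
        for spec in (s.utility_stable, s.utility_progression):
            assert (spec.low, spec.high, spec.family) == (0.0, 1.0, "beta")

    def test_every_nonzero_ae_probability(self, fixture_scenario):
        seen = {}
        for s in fixture_scenario.strategies:
            for ae in s.adverse_events:
                seen[(s.name, ae.name, ae.grade_band)] = ae.monthly_probability.base
        assert seen == AE_PROBS

    def test_every_ae_management_cost(self, fixture_scenario):
        for s in fixture_scenario.strategies:
            for ae in s.adverse_events:
                key = (s.name, ae.name, ae.grade_band)
                if key in AE_COSTS:
                    c = ae.management_cost
                    assert (c.base, c.low, c.high) == AE_COSTS[key], key
                    assert c.family == "gamma"
                else:
                    # hematologic events: no published management cost
                    assert ae.management_cost.base == 0.0
                    assert ae.management_cost.family == "fixed"

    def test_crossover_cost_equals_experimental_drug_price(self, fixture_scenario):
        dac = fixture_scenario.strategy("dacarbazine")
        dab = fixture_scenario.strategy("dabrafenib")
        assert dac.crossover_monthly_cost == dab.monthly_drug_cost.base == 7569.60
        assert fixture_scenario.strategy("vemurafenib").crossover_monthly_cost == 0.0

    def test_wtp_default(self, fixture_scenario):
        assert fixture_scenario.wtp_default == 100_000.0

    def test_ae_state_utilities_absent(self, fixture_scenario):
        for s in fixture_scenario.strategies:
            assert all(ae.ae_state_utility is None for ae in s.adverse_events)


class TestLoadScenarioValidation:
    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.yaml"):
            load_scenario(tmp_path / "nope.yaml")

    def test_missing_schema_version(self):
        doc = minimal_doc()
        del doc["schema_version"]
        with pytest.raises(ScenarioValidationError, match="schema_version"):
            parse_scenario(doc)

    def test_unknown_schema_version(self):
        with pytest.raises(ScenarioValidationError, match="schema_version"):
            parse_scenario(minimal_doc(schema_version=99))

    def test_unknown_top_level_key(self):
        with pytest.raises(ScenarioValidationError, match="unknown key"):
            parse_scenario(minimal_doc(bogus=1))

    def test_unknown_strategy_key(self):
        doc = minimal_doc()
        doc["strategies"][0]["typo_field"] = 1
        with pytest.raises(ScenarioValidationError, match=r"strategies\[0\]"):
            parse_scenario(doc)

    def test_utility_out_of_bounds_names_field(self):
        doc = minimal_doc()
        doc["strategies"][0]["utility_stable"] = {"base": 1.2, "family": "beta"}
        with pytest.raises(ScenarioValidationError, match="utility_stable"):
            parse_scenario(doc)

    def test_probability_out_of_range(self):
        doc = minimal_doc()
        doc["strategies"][0]["adverse_events"] = [
            {
                "name": "x",
                "grade_band": "g12",
                "monthly_probability": {"base": 1.5, "family": "fixed"},
                "management_cost": {"base": 10.0, "family": "fixed"},
            }
        ]
        with pytest.raises(ScenarioValidationError, match="monthly_probability"):
            parse_scenario(doc)

    def test_missing_survival_for_strategy(self):
        doc = minimal_doc(survival={})
        with pytest.raises(ScenarioValidationError, match="survival.a"):
            parse_scenario(doc)

    def test_duplicate_strategy_names(self):
        doc = minimal_doc()
        doc["strategies"].append(dict(doc["strategies"][0]))
        with pytest.raises(ScenarioValidationError, match="duplicate"):
            parse_scenario(doc)

    def test_missing_curve_csv_named_in_error(self, tmp_path):
        doc = minimal_doc()
        doc["survival"]["a"]["os"] = {"csv": "missing_curve.csv"}
        path = tmp_path / "scenario.yaml"
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(FileNotFoundError, match="missing_curve.csv"):
            load_scenario(path)

    def test_json_scenario_loads(self, tmp_path):
        import json

        path = tmp_path / "scenario.json"
        path.write_text(json.dumps(minimal_doc()))
        scenario = load_scenario(path)
        assert scenario.strategy_names == ["a"]


class TestRoundTrip:
    def test_scenario_round_trip_exact(self, fixture_scenario, tmp_path):
        out = tmp_path / "roundtrip.yaml"
        save_scenario(fixture_scenario, out)
        reloaded = load_scenario(out)
        assert scenario_to_dict(reloaded) == scenario_to_dict(fixture_scenario)

    def test_curve_csv_round_trip(self, tmp_path, fixture_scenario):
        curve = fixture_scenario.survival["dabrafenib"]["os"]
        path = tmp_path / "os.csv"
        write_curve_csv(curve, path)
        back = read_curve_csv(path, anchor_month=curve.anchor_month)
        np.testing.assert_array_equal(back.survival, curve.survival)


class TestWriteResults:
    def test_frontier_csv_columns_and_order(self, tmp_path):
        entries = [
            FrontierEntry("dear", 200.0, 0.5, "frontier", "cheap", 100.0, 0.2, 500.0),
            FrontierEntry("cheap", 100.0, 0.3, "frontier"),
        ]
        path = tmp_path / "frontier.csv"
        write_results(entries, path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "name", "total_cost", "total_qaly", "inc_cost", "inc_qaly", "icer", "status",
        ]
        assert list(df["name"]) == ["cheap", "dear"]

    def test_results_sorted_by_cost(self, tmp_path):
        results = [CEAResult("b", 50.0, 0.2), CEAResult("a", 10.0, 0.1)]
        path = tmp_path / "results.csv"
        write_results(results, path)
        df = pd.read_csv(path)
        assert list(df["name"]) == ["a", "b"]

    def test_empty_ceac_header_only(self, tmp_path):
        curve = CEACCurve(wtp_grid=np.array([]), proportions={"a": np.array([])})
        path = tmp_path / "ceac.csv"
        write_results(curve, path)
        assert path.read_text().strip() == "wtp,a"

    def test_round_trip_precision(self, tmp_path):
        results = [CEAResult("a", 15221.4567, 0.18201234)]
        path = tmp_path / "results.csv"
        write_results(results, path)
        df = pd.read_csv(path)
        assert df.loc[0, "total_cost"] == pytest.approx(15221.4567, abs=0.005)
        assert df.loc[0, "total_qaly"] == pytest.approx(0.18201234, abs=0.00005)

    def test_unwritable_path(self, tmp_path):
        with pytest.raises(OSError):
            write_results([CEAResult("a", 1.0, 0.1)], tmp_path / "no_dir" / "x.csv")
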