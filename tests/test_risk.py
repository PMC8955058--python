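"""Single-agent emetic-risk classification and the guideline rule tables."""

import logging

import pytest
from hypothesis import given, settings, strategies as st

from cinv_audit.risk import (DEFAULT_BSA_M2, Guideline, RiskCategory, Route,
                             RuleSchemaError, classify_single_agent,
                             compare_guidelines, dose_per_bsa,
                             load_drug_dictionary, load_guideline_table,
                             max_category, _read_single_agent_rows)
from guideline_fixtures import TABLE1_CELLS


class TestDosePerBsa:
    @pytest.mark.parametrize("dose,expected", [(2220, 1500), (0, 0), (370, 250)])
    def test_reference_bsa_conversion(self, dose, expected):
        assert dose_per_bsa(dose) == pytest.approx(expected)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            dose_per_bsa(-1)
        with pytest.raises(ValueError):
            dose_per_bsa(100, bsa_m2=0)


class TestSingleAgent:
    @pytest.mark.parametrize("drug,dose,route,expected", [
        ("cisplatin", 80, "IV", "high"),
        ("methotrexate", 59.2, "IV", "low"),          # 40 mg/m² < 50
        ("cyclophosphamide", 2960, "IV", "high"),     # 2000 mg/m² > 1500
        ("methotrexate", None, "PO", "minimal"),      # oral MTX is dose-free
        ("carboplatin", 600, "IV", "moderate"),
        ("bortezomib", None, "IV", "minimal"),
        ("never-seen-drug", None, "IV", "unknown"),
    ])
    def test_jsco_examples(self, drug, dose, route, expected):
        cat = classify_single_agent(drug, dose, route, Guideline.JSCO)
        assert cat == RiskCategory(expected)

    @pytest.mark.parametrize("mg_m2,expected", [
        (49.9, "low"), (50, "moderate"), (250, "moderate"), (250.1, "high"),
    ])
    def test_methotrexate_tier_boundaries(self, mg_m2, expected):
        """The 50-250 mg/m² band is closed; >250 escalates."""
        cat = classify_single_agent("methotrexate", mg_m2 * DEFAULT_BSA_M2, "IV")
        assert cat == RiskCategory(expected)

    @pytest.mark.parametrize("mg_m2,expected", [
        (1499.9, "moderate"), (1500, "moderate"), (1500.1, "high"),
    ])
    def test_cyclophosphamide_boundary_strict(self, mg_m2, expected):
        cat = classify_single_agent("cyclophosphamide", mg_m2 * DEFAULT_BSA_M2, "IV")
        assert cat == RiskCategory(expected)

    @pytest.mark.parametrize("mg_m2,expected", [
        (200, "low"), (200.1, "moderate"),
    ])
    def test_cytarabine_boundary_strict(self, mg_m2, expected):
        cat = classify_single_agent("cytarabine", mg_m2 * DEFAULT_BSA_M2, "IV")
        assert cat == RiskCategory(expected)

    def test_missing_dose_falls_back_to_middle_tier(self, caplog):
        with caplog.at_level(logging.WARNING, logger="cinv_audit.risk"):
            cat = classify_single_agent("methotrexate", None, "IV")
        assert cat == RiskCategory.MODERATE
        assert any("without a dose" in r.message for r in caplog.records)

    def test_missing_dose_configurable_to_unknown(self):
        cat = classify_single_agent("methotrexate", None, "IV",
                                    missing_dose="unknown")
        assert cat == RiskCategory.UNKNOWN

    def test_nccn_carboplatin_auc(self, caplog):
        assert classify_single_agent("carboplatin", None, "IV", "NCCN",
                                     auc=4.0) == RiskCategory.HIGH
        assert classify_single_agent("carboplatin", None, "IV", "NCCN",
                                     auc=3.9) == RiskCategory.MODERATE
        with caplog.at_level(logging.WARNING, logger="cinv_audit.risk"):
            cat = classify_single_agent("carboplatin", 600, "IV", "NCCN")
        assert cat == RiskCategory.MODERATE
        assert any("AUC" in r.message for r in caplog.records)

    def test_deterministic_total_function(self, jsco):
        for (drug, route) in list(jsco.single_agents)[:10]:
            first = classify_single_agent(drug, 100, route)
            assert classify_single_agent(drug, 100, route) == first

    @given(dose=st.floats(min_value=0, max_value=6000,
                          allow_nan=False, allow_infinity=False),
           bump=st.floats(min_value=0, max_value=3000,
                          allow_nan=False, allow_infinity=False))
    @settings(deadline=None, max_examples=60)
    def test_category_monotone_in_dose(self, dose, bump):
        """For dose-tiered drugs the category never drops as the dose rises."""
        for drug in ("methotrexate", "cyclophosphamide", "cytarabine"):
            lo = classify_single_agent(drug, dose, "IV")
            hi = classify_single_agent(drug, dose + bump, "IV")
            assert hi.rank >= lo.rank


class TestCompareGuidelines:
    @pytest.mark.parametrize("drug,dose,auc,guideline,expected", TABLE1_CELLS)
    def test_guideline_differences_grid(self, drug, dose, auc, guideline,
                                        expected):
        """Every printed cell of the between-guideline differences table."""
        result = compare_guidelines(drug, dose, auc=auc)
        assert result[Guideline(guideline)] == RiskCategory(expected)

    def test_shared_category_drug(self):
        assert set(compare_guidelines("cisplatin", 80).values()) == \
            {RiskCategory.HIGH}

    def test_cytarabine_threshold_divergence(self):
        """300 mg/m² clears the 200 threshold only where it applies."""
        result = compare_guidelines("cytarabine", 444)
        assert result[Guideline.JSCO] == RiskCategory.MODERATE
        assert result[Guideline.NCCN] == RiskCategory.MODERATE
        assert result[Guideline.ASCO] == RiskCategory.LOW
        assert result[Guideline.MASCC] == RiskCategory.LOW

    def test_cetuximab_split(self):
        result = compare_guidelines("cetuximab")
        assert {g.value: c.value for g, c in result.items()} == {
            "JSCO": "minimal", "ASCO": "low", "NCCN": "minimal", "MASCC": "low"}


class TestRuleTables:
    def test_tables_cover_the_published_drugs(self, jsco):
        for drug, route in [("cisplatin", Route.IV), ("s-1", Route.PO),
                            ("procarbazine", Route.PO), ("gefitinib", Route.PO),
                            ("nedaplatin", Route.IV), ("pertuzumab", Route.IV)]:
            assert jsco.get(drug, route) is not None

    def test_combination_rules_present(self, jsco):
        names = {r.name for r in jsco.combinations}
        assert {"FOLFOXIRI", "FOLFIRINOX", "GS", "GEM+nab-PTX", "ICE",
                "AC", "EC"} <= names

    def test_version_stamp(self, jsco):
        assert "rule tables" in jsco.version

    def test_malformed_file_names_row_and_column(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("drug_id,route,tier_bound,bound_op,bound_unit,category,"
                       "missing_dose_category\nfoo,IV,,,,not-a-category,\n")
        with bad.open() as fh:
            with pytest.raises(RuleSchemaError, match=r"row 2.*category"):
                _read_single_agent_rows(fh, Guideline.JSCO, "bad.csv")

    def test_wrong_header_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("a,b\n1,2\n")
        with bad.open() as fh:
            with pytest.raises(RuleSchemaError, match="header"):
                _read_single_agent_rows(fh, Guideline.JSCO, "bad.csv")


class TestMaxCategory:
    def test_unknown_never_wins(self):
        assert max_category([RiskCategory.UNKNOWN, RiskCategory.MINIMAL]) == \
            RiskCategory.MINIMAL
        assert max_category([RiskCategory.UNKNOWN]) == RiskCategory.UNKNOWN
        assert max_category([]) == RiskCategory.UNKNOWN

    def test_total_order(self):
        cats = [RiskCategory.MINIMAL, RiskCategory.HIGH, RiskCategory.LOW,
                RiskCategory.MODERATE]
        assert max_category(cats) == RiskCategory.HIGH


def test_drug_dictionary_maps_synonyms_and_classes():
    d = load_drug_dictionary()
    assert d["cddp"] == ("cisplatin", "chemotherapy")
    assert d["5-fu"] == ("fluorouracil", "chemotherapy")
    assert d["aprepitant"][1] == "NK1"
    assert d["granisetron"][1] == "serotonin_antagonist"
    assert d["psl"] == ("prednisolone", "steroid")
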