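import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardex.lab_values import (LabValue, Thresholds, extract_all, extract_blood_pressure,
                               extract_bmi, extract_lipids, extract_misc_bloods,
                               filter_by_threshold)


class TestBloodPressure:
    @pytest.mark.parametrize("text, s, d", [
        ("BP: 158/72", 158, 72),
        ("blood pressure 149/96", 149, 96),
        ("blood pressure elevated at 188/92", 188, 92),
        ("BP: 184/91.", 184, 91),
    ])
    def test_dialects(self, text, s, d):
        (v,) = extract_blood_pressure(text)
        assert (v.systolic, v.diastolic) == (s, d)

    def test_range_takes_per_component_maxima(self):
        (v,) = extract_blood_pressure("BP 120–130/88–92")
        assert (v.systolic, v.diastolic) == (130, 92)

    def test_plausibility_gate(self):
        assert extract_blood_pressure("BP: 20/10") == []
        assert extract_blood_pressure("BP: 400/90") == []

    def test_no_cue_no_match(self):
        assert extract_blood_pressure("ratio was 158/72") == []

    def test_span_contains_digits(self):
        (v,) = extract_blood_pressure("today blood pressure 149/96 noted")
        snippet = "today blood pressure 149/96 noted"[v.start:v.end]
        assert "149" in snippet and "96" in snippet


class TestLipidsAndBloods:
    def test_full_lipid_panel(self):
        vals = extract_lipids("lipid levels: total cholesterol 164, TG 145, HDL 33, and LDL 102")
        assert {(v.kind, v.value) for v in vals} == {
            ("TOTAL_CHOL", 164.0), ("TG", 145.0), ("HDL", 33.0), ("LDL", 102.0)
        }

    def test_single_analyte(self):
        (v,) = extract_lipids("LDL 102")
        assert (v.kind, v.value) == ("LDL", 102.0)

    def test_no_number_no_value(self):
        assert extract_lipids("lipids pending") == []
        assert extract_misc_bloods("glucose tolerance discussed") == []

    def test_blood_panel(self):
        vals = extract_misc_bloods("BUN is 27, creatinine is 4.7, and glucose is 79")
        assert {(v.kind, v.value) for v in vals} == {
            ("BUN", 27.0), ("CREATININE", 4.7), ("GLUCOSE", 79.0)
        }

    def test_a1c(self):
        (v,) = extract_misc_bloods("A1c 8.2")
        assert (v.kind, v.value) == ("A1C", 8.2)

    def test_bmi(self):
        (v,) = extract_bmi("BMI of 34.5")
        assert (v.kind, v.value) == ("BMI", 34.5)

    def test_extract_all_does_not_double_count_bp(self):
        vals = extract_all("BP: 158/72.")
        assert [v.kind for v in vals] == ["BP"]


def _bp(s, d):
    return LabValue("BP", s, d, "mmHg", 0, 1)


class TestThresholdFilter:
    def test_high_systolic_qualifies(self):
        ((v, rf, ind),) = filter_by_threshold([_bp(158, 72)])
        assert (rf, ind) == ("HYPERTENSION", "high blood pressure")

    def test_below_both_thresholds_dropped(self):
        assert filter_by_threshold([_bp(139, 89)]) == []

    def test_boundary_values_are_strict(self):
        assert filter_by_threshold([_bp(140, 90)]) == []

    def test_normal_glucose_dropped(self):
        v = LabValue("GLUCOSE", 79, None, "mg/dL", 0, 1)
        assert filter_by_threshold([v]) == []

    @pytest.mark.parametrize("kind, value, rf, ind", [
        ("A1C", 8.2, "DIABETES", "high A1c"),
        ("GLUCOSE", 200, "DIABETES", "high glucose"),
        ("TOTAL_CHOL", 260, "HYPERLIPIDEMIA", "high cholesterol"),
        ("LDL", 130, "HYPERLIPIDEMIA", "high LDL"),
        ("BMI", 32, "OBESITY", "BMI"),
    ])
    def test_promotions(self, kind, value, rf, ind):
        v = LabValue(kind, value, None, "", 0, 1)
        ((_, got_rf, got_ind),) = filter_by_threshold([v])
        assert (got_rf, got_ind) == (rf, ind)

    def test_irrelevant_kinds_never_promoted(self):
        vals = [LabValue(k, 999, None, "", 0, 1) for k in ("BUN", "CREATININE", "TG", "HDL")]
        assert filter_by_threshold(vals) == []

    @given(st.integers(100, 200), st.integers(50, 120))
    @settings(max_examples=200, deadline=None)
    def test_bp_filter_matches_brute_force_predicate(self, s, d):
        got = bool(filter_by_threshold([_bp(s, d)]))
        assert got == ((s > 140) or (d > 90))

    @given(st.integers(100, 200), st.integers(50, 120),
           st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_both_components(self, s, d, ds, dd):
        if filter_by_threshold([_bp(s, d)]):
            assert filter_by_threshold([_bp(s + ds, d + dd)])

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(systolic_high=0)
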