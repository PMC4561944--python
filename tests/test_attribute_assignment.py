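import pytest

from cardex import schema
from cardex.attribute_assignment import (RiskFactorAnnotation, assign_indicator,
                                         expand_continuing, featurize_time,
                                         load_indicator_rules)
from cardex.concept_recognition import ConceptMention, MedicationMention
from cardex.core_nlp import Document, process
from cardex.lab_values import LabValue
from cardex.sectionizer import TEXT, SectionedSentence


class TestIndicatorAssignment:
    def test_disease_mention(self):
        m = ConceptMention("DIABETES", 0, 15, "type 1 diabetes", "dictionary")
        assert assign_indicator(m) == ("DIABETES", "mention")

    def test_qualifying_a1c(self):
        triple = (LabValue("A1C", 8.2, None, "%", 0, 7), "DIABETES", "high A1c")
        assert assign_indicator(triple) == ("DIABETES", "high A1c")

    def test_medication_category(self):
        mm = MedicationMention("lisinopril", "ACE inhibitors", 0, 10)
        assert assign_indicator(mm) == ("MEDICATION", "ACE inhibitors")

    def test_cad_event_hint(self):
        m = ConceptMention("CAD", 0, 2, "MI", "abbreviation", "event")
        assert assign_indicator(m) == ("CAD", "event")

    def test_unknown_provenance_is_error(self):
        with pytest.raises(TypeError):
            assign_indicator("a bare string")

    def test_rule_ledger_loads_and_validates(self):
        rules = load_indicator_rules()
        assert len(rules) >= 10
        assert {r.provenance for r in rules} == {"disease", "lab", "medication"}


class TestExpandContinuing:
    def test_continuing_expands_to_all_three(self):
        assert expand_continuing(schema.CONTINUING) == frozenset(schema.TIME_ATTRS)

    @pytest.mark.parametrize("cls", schema.TIME_ATTRS)
    def test_singletons(self, cls):
        assert expand_continuing(cls) == frozenset({cls})

    def test_output_size_one_or_three(self):
        for cls in schema.TIME_CLASSES:
            assert len(expand_continuing(cls)) in (1, 3)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            expand_continuing("sometime")


class TestTimeFeatures:
    def test_section_and_indicator_readout(self):
        doc = Document(doc_id="d", text="aspirin 81mg")
        (ps,) = process(doc)
        ss = SectionedSentence(ps.sentence, TEXT, section_name="medications")
        fv = featurize_time((0, 7), "aspirin", ps, ss)
        assert fv.section_name == "medications"
        assert fv.indicator == "aspirin"
        assert fv.span_tokens == ("aspirin",)

    def test_sentence_start_gets_sentinel(self):
        doc = Document(doc_id="d", text="diabetes well controlled")
        (ps,) = process(doc)
        ss = SectionedSentence(ps.sentence, TEXT)
        fv = featurize_time((0, 8), "mention", ps, ss)
        assert fv.previous_word == "<none>"
        assert fv.next_word == "well"

    def test_previous_word_and_tag(self):
        doc = Document(doc_id="d", text="history of diabetes")
        (ps,) = process(doc)
        ss = SectionedSentence(ps.sentence, TEXT)
        fv = featurize_time((11, 19), "mention", ps, ss)
        assert fv.previous_word == "of"
        assert fv.previous_word_pos == "IN"


class TestAnnotationInvariants:
    def test_timeless_risk_factors_reject_time(self):
        with pytest.raises(ValueError):
            RiskFactorAnnotation(schema.SMOKER, "never",
                                 frozenset({schema.DURING_DCT}))

    def test_illegal_indicator_rejected(self):
        with pytest.raises(ValueError):
            RiskFactorAnnotation("DIABETES", "high blood pressure",
                                 frozenset({schema.DURING_DCT}))


class TestAssembly:
    def test_bp_sentence_yields_hypertension_annotation(self, pipe):
        doc = Document.from_text("d", "Record date: 2062-01-05\nVITAL SIGNS:\nBP: 158/72.\n")
        anns = pipe.extract(doc)
        hbp = [a for a in anns if a.indicator == "high blood pressure"]
        assert len(hbp) == 1
        assert hbp[0].risk_factor == "HYPERTENSION"
        assert 1 <= len(hbp[0].time_attrs) <= 3

    def test_empty_doc_gets_exactly_the_document_level_defaults(self, pipe):
        doc = Document.from_text("d", "Record date: 2062-01-05\nPLAN:\nFollow up in 3 months.\n")
        anns = pipe.extract(doc)
        assert {(a.risk_factor, a.indicator) for a in anns} == {
            (schema.SMOKER, "unknown"), (schema.FAMILY_HIST, "not present")
        }
        for a in anns:
            assert a.time_attrs == frozenset()

    def test_duplicate_mentions_merge(self, pipe):
        doc = Document.from_text(
            "d",
            "Record date: 2062-01-05\nPAST MEDICAL HISTORY:\n"
            "History of type 1 diabetes.\nKnown type 1 diabetes.\n",
        )
        anns = [a for a in pipe.extract(doc) if a.risk_factor == "DIABETES"]
        assert len(anns) == 1
        assert len(anns[0].spans) == 2

    def test_medication_section_override_gives_all_three_times(self, pipe):
        doc = Document.from_text(
            "d", "Record date: 2062-01-05\nMEDICATIONS:\nlisinopril 10 mg daily.\n")
        (a,) = [a for a in pipe.extract(doc) if a.risk_factor == schema.MEDICATION]
        assert a.time_attrs == frozenset(schema.TIME_ATTRS)

    def test_all_emitted_pairs_legal(self, pipe, heldout_notes):
        for note in heldout_notes[:8]:
            for a in pipe.extract(note.document):
                for t in a.time_attrs or {None}:
                    assert schema.is_legal(a.risk_factor, a.indicator, t)
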