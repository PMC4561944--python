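import pytest

from cardex.core_nlp import Document, Sentence
from cardex.sectionizer import (SECTION_HEADING, SECTION_HEADING_WITH_TEXT, TEXT,
                                SectionedSentence, _local_features,
                                apply_heading_override, classify_sections,
                                extract_section_name, featurize_sentence,
                                train_sectionizer)
from cardex.synthetic_data import sectionizer_training


class TestFeatures:
    def test_all_caps_heading(self, lex):
        fv = _local_features("CURRENT MEDICATIONS:", lex)
        assert fv.all_words_uppercased
        assert fv.contains_colon
        assert fv.dictionary_match
        assert not fv.ends_full_stop

    def test_record_date_line(self, lex):
        fv = _local_features("Record date: 2073-12-14", lex)
        assert fv.contains_colon
        assert not fv.all_words_uppercased

    def test_empty_sentence_all_false(self, lex):
        fv = _local_features("", lex)
        assert not any([fv.first_word_uppercased, fv.all_words_uppercased,
                        fv.all_words_lowercased, fv.dictionary_match,
                        fv.ends_full_stop, fv.contains_colon])
        assert fv.first_word == "" and fv.second_word == ""

    def test_neighbor_features_non_recursive(self, lex):
        feats = featurize_sentence("aspirin 81mg", "MEDICATIONS:", None, lex)
        assert "p:colon" in feats
        assert "EOS" in feats
        assert not any(f.startswith("p:p:") for f in feats)


class TestSectionName:
    @pytest.mark.parametrize("text, name", [
        ("Record date: 2073-12-14", "record date"),
        ("MEDICATIONS:", "medications"),
        ("Allergies: none : known", "allergies"),
    ])
    def test_text_before_first_colon(self, text, name):
        assert extract_section_name(text) == name

    def test_no_colon_falls_back_to_whole_text(self, caplog):
        assert extract_section_name("PLAN") == "plan"


def _ss(text, label):
    return SectionedSentence(Sentence(0, 0, len(text), text), label)


class TestHeadingOverride:
    def test_dictionary_text_relabeled(self, lex):
        out = apply_heading_override([_ss("past medical history", TEXT)], lex)
        assert out[0].label == SECTION_HEADING

    def test_ordinary_text_unchanged(self, lex):
        out = apply_heading_override([_ss("patient doing well", TEXT)], lex)
        assert out[0].label == TEXT

    def test_idempotent(self, lex):
        sents = [_ss("past medical history", TEXT), _ss("aspirin 81mg", TEXT)]
        once = apply_heading_override(sents, lex)
        labels_once = [s.label for s in once]
        twice = apply_heading_override(once, lex)
        assert [s.label for s in twice] == labels_once


class TestTraining:
    def test_empty_corpus_rejected(self, lex):
        with pytest.raises(ValueError):
            train_sectionizer([], lex)

    def test_missing_class_listed(self, lex):
        docs = [[("MEDICATIONS:", SECTION_HEADING), ("aspirin", TEXT)]]
        with pytest.raises(ValueError, match="SECTION_HEADING_WITH_TEXT"):
            train_sectionizer(docs, lex)

    def test_single_doc_with_all_classes_fits(self, lex):
        docs = [[
            ("Record date: 2073-12-14", SECTION_HEADING_WITH_TEXT),
            ("MEDICATIONS:", SECTION_HEADING),
            ("aspirin 81mg", TEXT),
        ]]
        model = train_sectionizer(docs, lex)
        assert set(model.labels) == {SECTION_HEADING, SECTION_HEADING_WITH_TEXT, TEXT}


class TestClassification:
    def test_heading_then_text(self, pipe, lex):
        doc = Document(doc_id="d", text="MEDICATIONS:\naspirin 81mg\n")
        out = classify_sections(doc, pipe.section_model, lex)
        assert [s.label for s in out] == [SECTION_HEADING, TEXT]
        assert out[1].section_name == "medications"

    def test_record_date_is_heading_with_text(self, pipe, lex):
        doc = Document(doc_id="d", text="Record date: 2073-12-14\n")
        (out,) = classify_sections(doc, pipe.section_model, lex)
        assert out.label == SECTION_HEADING_WITH_TEXT

    def test_plain_clinical_text(self, pipe, lex):
        doc = Document(doc_id="d", text="HPI:\ns/p XRT to esophagus\n")
        out = classify_sections(doc, pipe.section_model, lex)
        assert out[-1].label == TEXT

    def test_heldout_accuracy_at_least_090(self, pipe, lex, heldout_notes):
        correct = total = 0
        for note in heldout_notes:
            out = classify_sections(note.document, pipe.section_model, lex)
            gold = [lab for _, lab in note.sentence_labels]
            assert len(out) == len(gold)
            correct += sum(o.label == g for o, g in zip(out, gold))
            total += len(gold)
        assert correct / total >= 0.90

    def test_section_name_propagation_deterministic(self, pipe, lex, heldout_notes):
        doc = heldout_notes[0].document
        a = classify_sections(doc, pipe.section_model, lex)
        b = classify_sections(doc, pipe.section_model, lex)
        assert [(s.label, s.section_name) for s in a] == [(s.label, s.section_name) for s in b]
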