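"""End-to-end extraction: core NLP → recognizers → attribute assignment.

A :class:`Pipeline` bundles the lexicons, thresholds, and the three trained
models (sectionizer CRF, smoking NB, time NB) and turns a document into its
risk-factor annotation set.  Training helpers fit all three models from
generator-produced material in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import core_nlp
from .attribute_assignment import (RiskFactorAnnotation, assemble_annotations,
                                   train_time_nb)
from .concept_recognition import recognize_diseases, recognize_medications
from .core_nlp import Document
from .crf import ChainCRF
from .doc_classifiers import (classify_family_history, classify_smoking_sentence,
                              find_smoking_sentences, resolve_document_smoking,
                              train_smoking_nb)
from .lab_values import Thresholds, extract_all, filter_by_threshold
from .lexicons import LexiconSet, load_lexicons
from .nb import NaiveBayesModel
from .sectionizer import classify_sections, train_sectionizer


@dataclass
class Pipeline:
    lex: LexiconSet
    section_model: ChainCRF
    smoking_model: NaiveBayesModel
    time_model: NaiveBayesModel
    thresholds: Thresholds = field(default_factory=Thresholds)
    fh_age_threshold: float = 55.0

    def extract(self, doc: Document) -> list[RiskFactorAnnotation]:
        processed = core_nlp.process(doc)
        sectioned = classify_sections(doc, self.section_model, self.lex)

        mentions = recognize_diseases(doc, processed, self.lex)
        medications = recognize_medications(doc, processed, self.lex)
        labs = []
        for ps in processed:
            labs.extend(extract_all(ps.sentence.text, offset=ps.sentence.start))
        qualified = filter_by_threshold(labs, self.thresholds)

        plain = [ps.sentence for ps in processed]
        by_span = {(ps.sentence.start, ps.sentence.end): ps for ps in processed}
        smoking_sents = find_smoking_sentences(doc, plain, self.lex)
        classes = [
            classify_smoking_sentence(by_span[(s.start, s.end)], self.smoking_model)
            for s in smoking_sents
        ]
        smoking_status = resolve_document_smoking(classes)
        family_status = classify_family_history(doc, plain, self.lex,
                                                self.fh_age_threshold)

        return assemble_annotations(
            doc, processed, sectioned, mentions, qualified, medications,
            smoking_status, family_status, self.time_model, self.lex,
        )


def train_pipeline(
    section_docs: list[list[tuple[str, str]]],
    smoking_sentences: list[tuple[str, str]],
    time_examples,
    lex: LexiconSet | None = None,
    seed: int = 0,
    thresholds: Thresholds | None = None,
    fh_age_threshold: float = 55.0,
) -> Pipeline:
    """Fit all three learned components and assemble a ready pipeline.

    ``smoking_sentences`` are (sentence text, class) pairs; they are run
    through the core NLP stack to get the bag-of-words + POS features.
    """
    lex = lex or load_lexicons()
    section_model = train_sectionizer(section_docs, lex, seed=seed)
    labeled = []
    for text, cls in smoking_sentences:
        doc = Document(doc_id="train", text=text)
        processed = core_nlp.process(doc)
        if processed:
            labeled.append((processed[0], cls))
    smoking_model = train_smoking_nb(labeled, seed=seed)
    time_model = train_time_nb(time_examples, seed=seed)
    return Pipeline(lex, section_model, smoking_model, time_model,
                    thresholds or Thresholds(), fh_age_threshold)
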