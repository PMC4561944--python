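"""Document-level classifiers: smoking status and family history of
premature coronary artery disease.

Smoking is sentence-level Naive Bayes (bag of words + POS tags) over
sentences containing smoking-lexicon terms, resolved to one document status
by the priority current > past > never; a document with no smoking sentence
is "unknown".  The "ever" status is never emitted.

Family history is rule-based: a sentence with a CAD term and a
first-degree-relative term where the relative's age in a death/onset context
is below the premature-age cutoff (default 55 years, configurable) makes the
document "present"; otherwise "not present".
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .core_nlp import Document, ProcessedSentence, Sentence
from .lexicons import LexiconSet, _norm
from .nb import NaiveBayesModel, train_nb

SMOKING_CLASSES = ["current", "past", "never"]  # fixed tie-break order

PRESENT = "present"
NOT_PRESENT = "not present"


def _contains_term(text: str, terms: set[str]) -> bool:
    low = _norm(text)
    for t in terms:
        if " " in t or "-" in t:
            if t.replace("-", " ") in low.replace("-", " "):
                return True
        elif re.search(rf"(?<![a-z0-9]){re.escape(t)}(?![a-z0-9])", low):
            return True
    return False


def find_smoking_sentences(doc: Document, sentences: list[Sentence], lex: LexiconSet) -> list[Sentence]:
    """Sentences containing any smoking-lexicon term (case-insensitive)."""
    return [s for s in sentences if _contains_term(s.text, lex.smoking_terms)]


def smoking_features(ps: ProcessedSentence) -> list[str]:
    """Bag of lower-cased word tokens plus their POS tags."""
    feats = []
    for tok in ps.tokens:
        if any(c.isalnum() for c in tok.text):
            feats.append(tok.text.lower())
            feats.append("POS=" + tok.pos)
    return feats


def train_smoking_nb(
    labeled: list[tuple[ProcessedSentence, str]], seed: int = 0, alpha: float = 1.0
) -> NaiveBayesModel:
    """Fit the sentence-level smoking classifier (current/past/never)."""
    docs = [smoking_features(ps) for ps, _ in labeled]
    labels = [lab for _, lab in labeled]
    return train_nb(docs, labels, SMOKING_CLASSES, alpha=alpha)


def classify_smoking_sentence(ps: ProcessedSentence, model: NaiveBayesModel) -> str:
    return model.predict(smoking_features(ps))


def resolve_document_smoking(sentence_classes: list[str]) -> str:
    """One document status from per-sentence classes.

    Empty input means no smoking mention anywhere: "unknown".  Otherwise the
    priority current > past > never picks the status (permutation-invariant).
    """
    if not sentence_classes:
        return "unknown"
    for cls in SMOKING_CLASSES:
        if cls in sentence_classes:
            return cls
    raise ValueError(f"unexpected smoking classes: {sentence_classes}")


_CAD_TERMS = {"cad", "coronary artery disease", "coronary heart disease", "heart attack",
              "myocardial infarction", "mi"}
_AGE_RES = [
    re.compile(r"\bat\s+age\s+(\d{1,3})\b"),
    re.compile(r"\baged?\s+(\d{1,3})\b"),
    re.compile(r"\bat\s+(\d{1,3})\b"),
    re.compile(r"\bdied\b[^.]{0,40}?\b(\d{1,3})\b"),
    re.compile(r"\b(\d{1,3})\s*(?:years?\s+old|yo|y/o)\b"),
]


def _premature_age(text: str, threshold: float) -> bool:
    low = _norm(text)
    for pat in _AGE_RES:
        for m in pat.finditer(low):
            if float(m.group(1)) < threshold:
                return True
    return False


def classify_family_history(
    doc: Document,
    sentences: list[Sentence],
    lex: LexiconSet,
    age_threshold: float = 55.0,
) -> str:
    """"present" iff some sentence co-mentions CAD, a relative, and a
    premature age (< ``age_threshold``); otherwise "not present".

    A CAD+relative sentence with no parseable age is not premature.
    """
    for s in sentences:
        if (
            _contains_term(s.text, _CAD_TERMS)
            and _contains_term(s.text, lex.relation_terms)
            and _premature_age(s.text, age_threshold)
        ):
            return PRESENT
    return NOT_PRESENT
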