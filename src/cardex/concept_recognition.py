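"""Dictionary-driven recognition of disease-disorder and medication mentions.

Matching runs over raw sentence text with word-boundary anchoring; noun-phrase
chunks from the core NLP layer are used to extend medication matches to the
full phrase when looking up multiword generics.  Abbreviations (DM2, HTN, ASA)
and known misspellings (pravastain, obeise) resolve through the lexicon maps
before dictionary lookup.  Negated mentions are not suppressed — context
handling is an explicit non-goal of this version.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .core_nlp import Document, ProcessedSentence
from .lexicons import LexiconSet


def _key(matched: str) -> str:
    """Normalize matched surface text back to a lexicon key."""
    return re.sub(r"[\s\-]+", " ", matched.strip().lower())

DISEASE_RISK_FACTORS = ("CAD", "DIABETES", "HYPERLIPIDEMIA", "HYPERTENSION", "OBESITY")


@dataclass(frozen=True)
class ConceptMention:
    """A disease-disorder mention resolved to one of the five disease risk factors."""

    risk_factor: str
    start: int
    end: int
    matched_term: str
    source: str  # "dictionary" | "abbreviation"
    indicator_hint: str = "mention"  # "mention" | "event" | "test result" | "symptom"


@dataclass(frozen=True)
class MedicationMention:
    generic_name: str
    category: str
    start: int
    end: int


def _term_pattern(terms: list[str]) -> re.Pattern | None:
    """One alternation regex over all surface terms, longest-first, word-bounded."""
    if not terms:
        return None
    parts = sorted(terms, key=len, reverse=True)
    alts = "|".join(re.escape(t).replace(r"\ ", r"[\s\-]+") for t in parts)
    return re.compile(rf"(?<![A-Za-z0-9])(?:{alts})(?![A-Za-z0-9])", re.IGNORECASE)


def _surface_index(lex: LexiconSet) -> dict[str, tuple[str, str, str]]:
    """surface term -> (risk_factor, source, indicator_hint) for disease matching."""
    index: dict[str, tuple[str, str, str]] = {}
    for term, rf in lex.disease_terms.items():
        index[term] = (rf, "dictionary", "mention")
    for hint, terms in (
        ("event", lex.cad_event_terms),
        ("test result", lex.cad_test_terms),
        ("symptom", lex.cad_symptom_terms),
    ):
        for term in terms:
            index.setdefault(term, ("CAD", "dictionary", hint))
    # abbreviations and misspellings whose resolution lands on a disease term
    for short, long in lex.abbreviations.items():
        if long in index and short not in index:
            rf, _, hint = index[long]
            index[short] = (rf, "abbreviation", hint)
    for wrong, right in lex.misspellings.items():
        if right in lex.disease_terms and wrong not in index:
            index[wrong] = (lex.disease_terms[right], "dictionary", "mention")
    return index


def recognize_diseases(
    doc: Document, sentences: list[ProcessedSentence], lex: LexiconSet
) -> list[ConceptMention]:
    """All disease-disorder mentions mapping to the five disease risk factors.

    Overlapping matches of the same risk factor collapse to the longest;
    terms outside the five risk factors never enter the surface index, which
    is how irrelevant disorders are filtered out.
    """
    index = _surface_index(lex)
    pattern = _term_pattern(list(index))
    mentions: list[ConceptMention] = []
    if pattern is None:
        return mentions
    for ps in sentences:
        sent = ps.sentence
        for m in pattern.finditer(sent.text):
            rf, source, hint = index[_key(m.group())]
            mentions.append(
                ConceptMention(rf, sent.start + m.start(), sent.start + m.end(),
                               m.group(), source, hint)
            )
    return _collapse_overlaps(mentions)


def _collapse_overlaps(mentions: list[ConceptMention]) -> list[ConceptMention]:
    mentions = sorted(mentions, key=lambda m: (m.risk_factor, m.end - m.start), reverse=True)
    kept: list[ConceptMention] = []
    for m in mentions:
        if not any(
            k.risk_factor == m.risk_factor and m.start < k.end and k.start < m.end
            for k in kept
        ):
            kept.append(m)
    return sorted(kept, key=lambda m: (m.start, m.end))


def recognize_medications(
    doc: Document, sentences: list[ProcessedSentence], lex: LexiconSet
) -> list[MedicationMention]:
    """All medication-dictionary hits, each with its heart-disease category."""
    surfaces: dict[str, tuple[str, str]] = {}
    for name, cat in lex.medications.items():
        surfaces[name] = (name, cat)
    for short, long in lex.abbreviations.items():
        if long in lex.medications and short not in surfaces:
            surfaces[short] = (long, lex.medications[long])
    for wrong, right in lex.misspellings.items():
        if right in lex.medications and wrong not in surfaces:
            surfaces[wrong] = (right, lex.medications[right])
    pattern = _term_pattern(list(surfaces))
    hits: list[MedicationMention] = []
    if pattern is None:
        return hits
    seen_spans: list[tuple[int, int]] = []
    for ps in sentences:
        sent = ps.sentence
        for m in pattern.finditer(sent.text):
            span = (sent.start + m.start(), sent.start + m.end())
            if any(span[0] < e and s < span[1] for s, e in seen_spans):
                continue
            seen_spans.append(span)
            generic, cat = surfaces[_key(m.group())]
            hits.append(MedicationMention(generic, cat, span[0], span[1]))
    return hits
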