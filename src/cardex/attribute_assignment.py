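"""Indicator and time-attribute assignment.

Every recognized item (disease mention, qualifying lab value, medication
mention) gets an indicator attribute from a declarative rule ledger, then a
DCT-relative time attribute from a Naive Bayes classifier over the phrase,
its one-token neighborhood, the prevailing section name, and the indicator.
A phrase classified "continuing" expands to all three time attributes.
Medication mentions under a medication-list section heading are always
continuing — a deterministic override applied after the classifier.

Smoking status and family history are document-level tags with no time
attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from . import schema
from .concept_recognition import ConceptMention, MedicationMention
from .core_nlp import Document, ProcessedSentence
from .lab_values import LabValue
from .lexicons import LexiconSet
from .nb import NaiveBayesModel, train_nb
from .sectionizer import SectionedSentence

TIME_CLASS_ORDER = [
    schema.BEFORE_DCT,
    schema.DURING_DCT,
    schema.AFTER_DCT,
    schema.CONTINUING,
]

_SENTINEL = "<none>"


@dataclass(frozen=True)
class RiskFactorAnnotation:
    risk_factor: str
    indicator: str
    time_attrs: frozenset[str]
    spans: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.risk_factor in schema.TIMELESS:
            if self.time_attrs:
                raise ValueError(f"{self.risk_factor} must carry no time attribute")
            schema.validate(self.risk_factor, self.indicator)
        else:
            if not 1 <= len(self.time_attrs) <= 3:
                raise ValueError("need 1-3 time attributes")
            for t in self.time_attrs:
                schema.validate(self.risk_factor, self.indicator, t)


# --- indicator rule ledger -------------------------------------------------

@dataclass(frozen=True)
class IndicatorRule:
    provenance: str  # disease | lab | medication
    selector: str
    risk_factor: str  # "*" = from the item
    indicator: str  # "category" = the medication category


def load_indicator_rules(path: str | Path | None = None) -> list[IndicatorRule]:
    """Load and validate the ordered indicator-assignment rule ledger."""
    p = Path(path) if path else Path(str(resources.files("cardex").joinpath("data/indicator_rules.tsv")))
    rules = []
    for lineno, raw in enumerate(p.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise ValueError(f"{p}:{lineno}: expected 4 columns, got {len(cols)}")
        rule = IndicatorRule(*cols)
        if rule.risk_factor != "*" and rule.indicator not in ("category",):
            schema.validate(rule.risk_factor, rule.indicator)
        rules.append(rule)
    return rules


_RULES: list[IndicatorRule] | None = None


def _rules() -> list[IndicatorRule]:
    global _RULES
    if _RULES is None:
        _RULES = load_indicator_rules()
    return _RULES


def assign_indicator(item) -> tuple[str, str]:
    """(risk factor, indicator) for a recognized item via the rule ledger."""
    if isinstance(item, ConceptMention):
        provenance, selector = "disease", item.indicator_hint
    elif isinstance(item, MedicationMention):
        provenance, selector = "medication", item.category
    elif isinstance(item, tuple) and len(item) == 3 and isinstance(item[0], LabValue):
        provenance, selector = "lab", item[0].kind
    else:
        raise TypeError(f"item of unknown provenance: {item!r}")
    for rule in _rules():
        if rule.provenance != provenance:
            continue
        if rule.selector not in ("*", selector):
            continue
        if provenance == "disease":
            rf = item.risk_factor if rule.risk_factor == "*" else rule.risk_factor
            return rf, rule.indicator
        if provenance == "medication":
            return rule.risk_factor, item.category
        lab, rf, indicator = item
        return rf, indicator
    raise TypeError(f"no indicator rule matches {provenance}/{selector}")


# --- time-attribute features and classifier --------------------------------

@dataclass(frozen=True)
class TimeFeatureVector:
    span_tokens: tuple[str, ...]
    previous_word: str
    previous_word_pos: str
    next_word: str
    next_word_pos: str
    section_name: str
    indicator: str

    def as_features(self) -> list[str]:
        feats = [t.lower() for t in self.span_tokens]
        feats += [
            "PW=" + self.previous_word.lower(),
            "PP=" + self.previous_word_pos,
            "NW=" + self.next_word.lower(),
            "NP=" + self.next_word_pos,
            "SEC=" + self.section_name,
            "IND=" + self.indicator,
        ]
        return feats


def featurize_time(
    span: tuple[int, int],
    indicator: str,
    ps: ProcessedSentence,
    sectioned: SectionedSentence,
) -> TimeFeatureVector:
    """Feature template for one risk-factor phrase occurrence."""
    start, end = span
    inside = [t for t in ps.tokens if t.start >= start and t.end <= end]
    before = [t for t in ps.tokens if t.end <= start]
    after = [t for t in ps.tokens if t.start >= end]
    prev = before[-1] if before else None
    nxt = after[0] if after else None
    return TimeFeatureVector(
        span_tokens=tuple(t.text for t in inside),
        previous_word=prev.text if prev else _SENTINEL,
        previous_word_pos=prev.pos if prev else _SENTINEL,
        next_word=nxt.text if nxt else _SENTINEL,
        next_word_pos=nxt.pos if nxt else _SENTINEL,
        section_name=sectioned.section_name or _SENTINEL,
        indicator=indicator,
    )


def train_time_nb(
    labeled: list[tuple[TimeFeatureVector, str]], seed: int = 0, alpha: float = 1.0
) -> NaiveBayesModel:
    """Fit the 4-class time classifier (before/during/after DCT, continuing)."""
    docs = [fv.as_features() for fv, _ in labeled]
    labels = [lab for _, lab in labeled]
    return train_nb(docs, labels, TIME_CLASS_ORDER, alpha=alpha)


def classify_time(fv: TimeFeatureVector, model: NaiveBayesModel) -> str:
    return model.predict(fv.as_features())


def expand_continuing(time_class: str) -> frozenset[str]:
    """"continuing" becomes all three time attributes; others stay singleton."""
    if time_class == schema.CONTINUING:
        return frozenset(schema.TIME_ATTRS)
    if time_class not in schema.TIME_ATTRS:
        raise ValueError(f"unknown time class: {time_class}")
    return frozenset({time_class})


# --- assembly --------------------------------------------------------------

def _containing(sectioned: list[SectionedSentence], processed: list[ProcessedSentence],
                start: int) -> tuple[ProcessedSentence, SectionedSentence] | None:
    for ps, ss in zip(processed, sectioned):
        if ps.sentence.start <= start < ps.sentence.end:
            return ps, ss
    return None


def assemble_annotations(
    doc: Document,
    processed: list[ProcessedSentence],
    sectioned: list[SectionedSentence],
    mentions: list[ConceptMention],
    qualified_labs: list[tuple[LabValue, str, str]],
    medications: list[MedicationMention],
    smoking_status: str,
    family_status: str,
    time_model: NaiveBayesModel,
    lex: LexiconSet,
) -> list[RiskFactorAnnotation]:
    """Merge all recognizer outputs into the document's annotation set.

    Every item gets its indicator, a time class (with the medication-section
    override), and the expanded time set; duplicates with identical
    (risk factor, indicator, time set) merge with unioned spans.  Smoking and
    family-history tags are always emitted, once each, with no time attribute.
    """
    merged: dict[tuple[str, str, frozenset[str]], list[tuple[int, int]]] = {}

    items: list[tuple[object, tuple[int, int]]] = []
    for m in mentions:
        items.append((m, (m.start, m.end)))
    for triple in qualified_labs:
        items.append((triple, (triple[0].start, triple[0].end)))
    for mm in medications:
        items.append((mm, (mm.start, mm.end)))

    for item, span in items:
        rf, indicator = assign_indicator(item)
        ctx = _containing(sectioned, processed, span[0])
        if ctx is None:
            continue
        ps, ss = ctx
        fv = featurize_time(span, indicator, ps, ss)
        time_class = classify_time(fv, time_model)
        if rf == schema.MEDICATION and (ss.section_name or "") in lex.med_section_headings:
            time_class = schema.CONTINUING
        key = (rf, indicator, expand_continuing(time_class))
        merged.setdefault(key, []).append(span)

    annotations = [
        RiskFactorAnnotation(rf, ind, times, tuple(sorted(spans)))
        for (rf, ind, times), spans in merged.items()
    ]
    annotations.append(RiskFactorAnnotation(schema.SMOKER, smoking_status, frozenset()))
    annotations.append(RiskFactorAnnotation(schema.FAMILY_HIST, family_status, frozenset()))
    return sorted(annotations, key=lambda a: (a.risk_factor, a.indicator, sorted(a.time_attrs)))
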