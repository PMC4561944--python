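"""Section segmentation: a chain-CRF sentence classifier with rule overrides.

Each sentence of a note is labeled SECTION_HEADING, SECTION_HEADING_WITH_TEXT,
or TEXT.  The feature template is fixed: first-word/all-words casing, section
dictionary match, first and second word, trailing full stop, colon presence,
plus the previous and next sentences' own local features.  After decoding, a
dictionary override relabels TEXT sentences that are verbatim heading terms,
and the prevailing section name is propagated forward from the most recent
heading (text before the first colon, lower-cased).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core_nlp import Document, Sentence, split_sentences
from .crf import ChainCRF, train_crf
from .lexicons import LexiconSet, _norm

logger = logging.getLogger(__name__)

SECTION_HEADING = "SECTION_HEADING"
SECTION_HEADING_WITH_TEXT = "SECTION_HEADING_WITH_TEXT"
TEXT = "TEXT"
LABELS = (SECTION_HEADING, SECTION_HEADING_WITH_TEXT, TEXT)


@dataclass
class SectionedSentence:
    sentence: Sentence
    label: str
    section_name: str | None = None


@dataclass(frozen=True)
class SectionFeatureVector:
    first_word_uppercased: bool = False
    all_words_uppercased: bool = False
    all_words_lowercased: bool = False
    dictionary_match: bool = False
    first_word: str = ""
    second_word: str = ""
    ends_full_stop: bool = False
    contains_colon: bool = False

    def as_features(self, prefix: str = "") -> set[str]:
        feats = set()
        if self.first_word_uppercased:
            feats.add(prefix + "first_upper")
        if self.all_words_uppercased:
            feats.add(prefix + "all_upper")
        if self.all_words_lowercased:
            feats.add(prefix + "all_lower")
        if self.dictionary_match:
            feats.add(prefix + "dict_match")
        if self.first_word:
            feats.add(prefix + "fw=" + self.first_word.lower())
        if self.second_word:
            feats.add(prefix + "sw=" + self.second_word.lower())
        if self.ends_full_stop:
            feats.add(prefix + "full_stop")
        if self.contains_colon:
            feats.add(prefix + "colon")
        return feats


def _local_features(text: str, lex: LexiconSet) -> SectionFeatureVector:
    words = text.split()
    alpha = [w for w in words if any(c.isalpha() for c in w)]
    head = text.split(":")[0] if ":" in text else text
    return SectionFeatureVector(
        first_word_uppercased=bool(words) and words[0][:1].isupper(),
        all_words_uppercased=bool(alpha) and all(w.isupper() for w in alpha),
        all_words_lowercased=bool(alpha) and all(w.islower() for w in alpha),
        dictionary_match=_norm(head.rstrip(":. ")) in lex.section_headings
        or any(h in _norm(text) for h in lex.section_headings),
        first_word=words[0] if words else "",
        second_word=words[1] if len(words) > 1 else "",
        ends_full_stop=text.rstrip().endswith("."),
        contains_colon=":" in text,
    )


def featurize_sentence(
    sentence_text: str,
    prev_text: str | None,
    next_text: str | None,
    lex: LexiconSet,
) -> set[str]:
    """The full CRF feature set: local features plus both neighbors' locals."""
    feats = _local_features(sentence_text, lex).as_features()
    feats.add("bias")
    if prev_text is None:
        feats.add("BOS")
    else:
        feats |= _local_features(prev_text, lex).as_features("p:")
    if next_text is None:
        feats.add("EOS")
    else:
        feats |= _local_features(next_text, lex).as_features("n:")
    return feats


def _doc_feature_sequence(sentences: list[str], lex: LexiconSet) -> list[set[str]]:
    out = []
    for i, text in enumerate(sentences):
        prev = sentences[i - 1] if i > 0 else None
        nxt = sentences[i + 1] if i + 1 < len(sentences) else None
        out.append(featurize_sentence(text, prev, nxt, lex))
    return out


def train_sectionizer(
    labeled_docs: list[list[tuple[str, str]]],
    lex: LexiconSet,
    seed: int = 0,
    c2: float = 0.1,
) -> ChainCRF:
    """Fit the chain CRF on documents given as [(sentence_text, label), ...].

    ``seed`` is recorded for provenance; the optimization itself is
    deterministic in the training data order.
    """
    seen = {lab for doc in labeled_docs for _, lab in doc}
    missing = [l for l in LABELS if l not in seen]
    if missing:
        raise ValueError(f"training corpus lacks classes: {missing}")
    seqs = [_doc_feature_sequence([s for s, _ in doc], lex) for doc in labeled_docs]
    labs = [[l for _, l in doc] for doc in labeled_docs]
    model = train_crf(seqs, labs, c2=c2)
    logger.info("sectionizer trained: %d docs, seed=%d, hash=%s",
                len(labeled_docs), seed, model.model_hash()[:12])
    return model


def extract_section_name(sentence_text: str) -> str:
    """Lower-cased, trimmed text before the first colon.

    A heading without a colon returns the whole lower-cased text (warned).
    """
    if ":" in sentence_text:
        return sentence_text.split(":", 1)[0].strip().lower()
    logger.warning("heading sentence has no colon: %r", sentence_text)
    return sentence_text.strip().lower()


def apply_heading_override(
    sectioned: list[SectionedSentence], lex: LexiconSet
) -> list[SectionedSentence]:
    """Relabel TEXT sentences that are verbatim heading-dictionary terms."""
    for ss in sectioned:
        if ss.label == TEXT and _norm(ss.sentence.text.rstrip(":. ")) in lex.section_headings:
            ss.label = SECTION_HEADING
    _propagate_names(sectioned)
    return sectioned


def _heading_name(text: str) -> str:
    return extract_section_name(text) if ":" in text else text.rstrip(":. ").strip().lower()


def _propagate_names(sectioned: list[SectionedSentence]) -> None:
    current: str | None = None
    for ss in sectioned:
        if ss.label == SECTION_HEADING:
            current = _heading_name(ss.sentence.text)
            ss.section_name = current
        elif ss.label == SECTION_HEADING_WITH_TEXT:
            current = _heading_name(ss.sentence.text)
            ss.section_name = current
        else:
            ss.section_name = current


def classify_sections(doc: Document, model: ChainCRF, lex: LexiconSet) -> list[SectionedSentence]:
    """Label every sentence and resolve the prevailing section name."""
    sentences = split_sentences(doc.text)
    if not sentences:
        return []
    seq = _doc_feature_sequence([s.text for s in sentences], lex)
    labels = model.decode(seq)
    sectioned = [SectionedSentence(s, l) for s, l in zip(sentences, labels)]
    return apply_heading_override(sectioned, lex)
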