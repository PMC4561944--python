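"""Core NLP layer: sentence detection, tokenization, POS tagging, NP chunking.

Clinical notes are line-oriented: headings ("MEDICATIONS:"), record-date
headers and list items each sit on their own line, so newlines are hard
sentence boundaries; within a line, sentences split at full stops.  The POS
tagger is a deterministic lexicon + suffix tagger emitting Penn-style tags —
downstream components only rely on the coarse noun/verb/number distinction.

Offsets are 0-based, half-open, in characters of the raw document text, so
``doc.text[s.start:s.end] == s.text`` for every sentence and token.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date, datetime

logger = logging.getLogger(__name__)

RECORD_DATE_RE = re.compile(r"record date\s*:\s*(\d{4}-\d{2}-\d{2})", re.IGNORECASE)


@dataclass(frozen=True)
class Document:
    """One clinical note with its document creation time (DCT)."""

    doc_id: str
    text: str
    patient_id: str = ""
    dct: date | None = None

    @classmethod
    def from_text(cls, doc_id: str, text: str, patient_id: str = "") -> "Document":
        """Build a document, parsing the DCT from a ``Record date:`` header."""
        m = RECORD_DATE_RE.search(text)
        dct = None
        if m:
            try:
                dct = datetime.strptime(m.group(1), "%Y-%m-%d").date()
            except ValueError:
                pass
        if dct is None:
            logger.warning("document %s has no parseable record-date header", doc_id)
        return cls(doc_id=doc_id, text=text, patient_id=patient_id, dct=dct)


@dataclass(frozen=True)
class Sentence:
    index: int
    start: int
    end: int
    text: str


@dataclass
class Token:
    start: int
    end: int
    text: str
    pos: str = ""


# A full stop splits a sentence when followed by whitespace and more text;
# decimals (4.7) never match because the period is not followed by a space.
_INLINE_SPLIT_RE = re.compile(r"(?<=[.!?])\s+(?=\S)")


def split_sentences(text: str) -> list[Sentence]:
    """Split note text into ordered, non-overlapping sentences.

    Newlines always terminate a sentence (headings and list items are
    isolated for the sectionizer); periods split within a line.
    """
    sentences: list[Sentence] = []
    offset = 0
    for line in text.split("\n"):
        stripped = line.strip()
        if stripped:
            line_start = offset + (len(line) - len(line.lstrip()))
            _split_line(stripped, line_start, sentences)
        offset += len(line) + 1
    return sentences


def _split_line(line: str, start: int, out: list[Sentence]) -> None:
    pos = 0
    for m in _INLINE_SPLIT_RE.finditer(line):
        piece = line[pos : m.start()]
        if piece.strip():
            out.append(Sentence(len(out), start + pos, start + m.start(), piece))
        pos = m.end()
    piece = line[pos:]
    if piece.strip():
        out.append(Sentence(len(out), start + pos, start + len(line), piece))


# Words (incl. alphanumerics like DM2, A1c), numbers with decimals, or any
# single non-space character.  "158/72" tokenizes as ("158", "/", "72").
_TOKEN_RE = re.compile(r"\d+(?:\.\d+)?|[A-Za-z](?:[A-Za-z0-9']*[A-Za-z0-9])?|\S")


def tokenize(sentence: Sentence) -> list[Token]:
    """Split a sentence into word/number/punctuation tokens with doc offsets."""
    return [
        Token(sentence.start + m.start(), sentence.start + m.end(), m.group())
        for m in _TOKEN_RE.finditer(sentence.text)
    ]


_VERB_STEMS = {
    "be", "is", "was", "are", "were", "been", "has", "have", "had", "do", "does",
    "did", "deny", "denies", "denied", "smoke", "quit", "stop", "start", "take",
    "continue", "discontinue", "use", "report", "present", "complain", "die",
    "live", "drink", "feel", "follow", "recommend", "prescribe", "increase",
    "decrease", "hold", "resume", "will", "may", "should", "can", "remain",
    "appear", "include", "show", "reveal", "check", "monitor", "see", "note",
    "elevate", "improve", "control", "manage", "tolerate", "admit", "discharge",
}
_DETS = {"a", "an", "the", "this", "that", "these", "those", "his", "her", "their"}
_PREPS = {
    "of", "in", "on", "at", "to", "for", "with", "without", "by", "from",
    "under", "over", "since", "per", "during", "after", "before",
}
_CONJ = {"and", "or", "but"}
_PRONOUNS = {"he", "she", "they", "it", "i", "we", "you", "pt", "patient"}
_ADVERBS = {"not", "no", "never", "currently", "daily", "now", "ago", "well", "still"}
_ADJ_SUFFIXES = ("ive", "ous", "able", "ible", "ful", "ic", "al")


def _tag_word(word: str, prev_tag: str) -> str:
    low = word.lower()
    if re.fullmatch(r"\d+(?:\.\d+)?", word):
        return "CD"
    if not word[0].isalpha():
        return word if word in {".", ",", ":", ";"} else "SYM"
    if low in _DETS:
        return "DT"
    if low in _PREPS:
        return "IN"
    if low in _CONJ:
        return "CC"
    if low in _ADVERBS:
        return "RB"
    if low in {"patient", "pt"}:
        return "NN"
    if low in _PRONOUNS:
        return "PRP"
    if low in _VERB_STEMS:
        return "VB"
    for stem in _VERB_STEMS:
        if low in (stem + "s", stem + "es", stem + "d", stem + "ed", stem + "ing"):
            if low.endswith("ing"):
                return "VBG"
            if low.endswith(("d", "ed")):
                return "VBD"
            return "VBZ"
    if low.endswith("ly"):
        return "RB"
    if low.endswith(_ADJ_SUFFIXES) and prev_tag in {"DT", "VB", "VBZ", "VBD", ""}:
        return "JJ"
    return "NN"


def pos_tag(tokens: list[Token]) -> list[Token]:
    """Fill ``pos`` on each token in place (also returned for chaining)."""
    prev = ""
    for tok in tokens:
        tok.pos = _tag_word(tok.text, prev)
        prev = tok.pos
    return tokens


_NP_INNER = {"DT", "JJ", "CD", "NN"}


def chunk_noun_phrases(tagged: list[Token]) -> list[tuple[int, int]]:
    """Maximal noun-phrase character spans over a POS-tagged sentence.

    A chunk is a maximal run of determiner/adjective/number/noun tokens
    containing at least one noun; these are the candidate windows for
    concept recognition.
    """
    chunks: list[tuple[int, int]] = []
    run: list[Token] = []
    for tok in tagged + [Token(0, 0, "", "EOS")]:
        if tok.pos in _NP_INNER:
            run.append(tok)
        else:
            if any(t.pos == "NN" for t in run):
                chunks.append((run[0].start, run[-1].end))
            run = []
    return chunks


@dataclass
class ProcessedSentence:
    """A sentence with its tokens (POS-filled) and noun-phrase chunks."""

    sentence: Sentence
    tokens: list[Token] = field(default_factory=list)
    chunks: list[tuple[int, int]] = field(default_factory=list)


def process(doc: Document) -> list[ProcessedSentence]:
    """Run the full core-NLP stack over one document."""
    out = []
    for sent in split_sentences(doc.text):
        toks = pos_tag(tokenize(sent))
        out.append(ProcessedSentence(sent, toks, chunk_noun_phrases(toks)))
    return out
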