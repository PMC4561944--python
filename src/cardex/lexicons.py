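"""Custom dictionaries backing recognition: disease terms, abbreviations,
a medication dictionary (generic name → heart-disease category), smoking
terms, section headings, family-relation terms, and a misspelling map.

Files are plain text under a lexicon directory: two-column TSV for maps,
one term per line for sets; ``#`` starts a comment.  The shipped defaults
live in ``cardex/data/lexicons`` and every file can be overridden.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from . import schema

logger = logging.getLogger(__name__)


class LexiconError(ValueError):
    """Fatal configuration error while loading lexicon files."""


def _norm(term: str) -> str:
    return re.sub(r"\s+", " ", term.strip().lower())


@dataclass
class LexiconSet:
    disease_terms: dict[str, str] = field(default_factory=dict)
    abbreviations: dict[str, str] = field(default_factory=dict)
    medications: dict[str, str] = field(default_factory=dict)
    smoking_terms: set[str] = field(default_factory=set)
    section_headings: set[str] = field(default_factory=set)
    relation_terms: set[str] = field(default_factory=set)
    misspellings: dict[str, str] = field(default_factory=dict)
    med_section_headings: set[str] = field(default_factory=set)
    cad_event_terms: set[str] = field(default_factory=set)
    cad_test_terms: set[str] = field(default_factory=set)
    cad_symptom_terms: set[str] = field(default_factory=set)

    def medication_categories(self) -> set[str]:
        return set(self.medications.values())


_MAP_FILES = {
    "disease_terms": "disease_terms.tsv",
    "abbreviations": "abbreviations.tsv",
    "medications": "medications.tsv",
    "misspellings": "misspellings.tsv",
}
_SET_FILES = {
    "smoking_terms": "smoking_terms.txt",
    "section_headings": "section_headings.txt",
    "relation_terms": "relation_terms.txt",
    "med_section_headings": "med_section_headings.txt",
    "cad_event_terms": "cad_event_terms.txt",
    "cad_test_terms": "cad_test_terms.txt",
    "cad_symptom_terms": "cad_symptom_terms.txt",
}


def default_lexicon_dir() -> Path:
    return Path(str(resources.files("cardex").joinpath("data/lexicons")))


def _read_lines(path: Path) -> list[tuple[int, str]]:
    if not path.is_file():
        raise LexiconError(f"missing lexicon file: {path}")
    out = []
    for i, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if line and not line.startswith("#"):
            out.append((i, line))
    return out


def _load_map(path: Path, norm_values: bool = True) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for lineno, line in _read_lines(path):
        cols = line.split("\t")
        if len(cols) != 2:
            raise LexiconError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(cols)}"
            )
        mapping[_norm(cols[0])] = _norm(cols[1]) if norm_values else cols[1].strip()
    return mapping


def _load_set(path: Path) -> set[str]:
    return {_norm(line) for _, line in _read_lines(path)}


def load_lexicons(lexicon_dir: str | Path | None = None) -> LexiconSet:
    """Load all lexicon files from ``lexicon_dir`` (shipped defaults if None).

    Validates that medication categories are legal schema values, that the
    abbreviation map is acyclic (no expansion is itself a short form), and
    that disease terms map to known risk factors.
    """
    base = Path(lexicon_dir) if lexicon_dir is not None else default_lexicon_dir()
    lex = LexiconSet()
    for attr, fname in _MAP_FILES.items():
        # disease risk-factor codes and medication category names keep case
        norm_values = attr in ("abbreviations", "misspellings")
        setattr(lex, attr, _load_map(base / fname, norm_values=norm_values))
    for attr, fname in _SET_FILES.items():
        setattr(lex, attr, _load_set(base / fname))

    for term, rf in lex.disease_terms.items():
        if rf not in schema.RISK_FACTORS:
            raise LexiconError(f"disease term {term!r} maps to unknown risk factor {rf!r}")
    for name, cat in lex.medications.items():
        if cat not in schema.MEDICATION_CATEGORIES:
            raise LexiconError(f"medication {name!r} has unknown category {cat!r}")
    cyclic = set(lex.abbreviations) & {_norm(v) for v in lex.abbreviations.values()}
    if cyclic:
        raise LexiconError(f"abbreviation map is not acyclic: {sorted(cyclic)}")

    logger.info(
        "lexicons loaded from %s: %d disease terms, %d abbreviations, "
        "%d medications in %d categories, %d smoking terms, %d headings",
        base, len(lex.disease_terms), len(lex.abbreviations), len(lex.medications),
        len(lex.medication_categories()), len(lex.smoking_terms),
        len(lex.section_headings),
    )
    return lex


def expand_abbreviation(term: str, lex: LexiconSet) -> str:
    """Canonical long form for a known short form, else the input unchanged."""
    return lex.abbreviations.get(_norm(term), term)


def correct_misspelling(token: str, lex: LexiconSet) -> str:
    """Corrected form when the token is in the misspelling map, else unchanged."""
    return lex.misspellings.get(_norm(token), token)


def lookup_medication(phrase: str, lex: LexiconSet) -> tuple[str, str] | None:
    """Longest medication-dictionary match within a phrase.

    Tokens are misspelling-corrected and n-grams abbreviation-expanded before
    lookup, so "ASA 81 mg daily" resolves to ("aspirin", "aspirin").
    """
    words = [correct_misspelling(w, lex) for w in _norm(phrase).split(" ")]
    best: tuple[str, str] | None = None
    best_len = 0
    for n in range(len(words), 0, -1):
        for i in range(len(words) - n + 1):
            gram = " ".join(words[i : i + n])
            gram = expand_abbreviation(gram, lex)
            if gram in lex.medications and n > best_len:
                best, best_len = (gram, lex.medications[gram]), n
    return best
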