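"""Seeded generator of synthetic clinical notes with known gold tags.

Each note mimics the structure the extraction pipeline consumes: a record-date
header, a handful of headed sections, lab-value sentences in several surface
dialects, a medication list, smoking and family-history statements, plus
abbreviation and misspelling noise.  Gold tags are computed from the planting
decisions with the generator's own inline threshold arithmetic — it shares no
code path with the extractor, so agreement between the two is a real check.

The generator also emits labeled training material for the three learned
components (sectionizer CRF, smoking Naive Bayes, time-attribute Naive
Bayes); labels follow the planting templates, making the classes separable
by construction at default noise.

What this corpus does not emulate: free narrative prose, negation, OCR noise,
inconsistent section vocabularies, or cross-note patient timelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import core_nlp, schema
from .attribute_assignment import TimeFeatureVector, featurize_time
from .core_nlp import Document
from .io_eval import GoldTag, write_annotations
from .sectionizer import (SECTION_HEADING, SECTION_HEADING_WITH_TEXT, TEXT,
                          SectionedSentence)


@dataclass
class GenConfig:
    """Study conditions for the synthetic corpus.

    Inclusion probabilities are per note; lab values are sampled uniformly
    over clinically plausible ranges wide enough to fall on both sides of
    the guideline cutoffs.  ``seed`` is mandatory.
    """

    seed: int
    n_patients: int = 10
    notes_per_patient: int = 3
    p_bp: float = 0.5
    p_lipids: float = 0.4
    p_bloods: float = 0.4
    p_bmi: float = 0.3
    p_disease_mention: float = 0.8
    p_disease_before: float = 0.3
    p_medication: float = 0.8
    p_plan_med: float = 0.3
    p_smoking: float = 0.7
    p_family_history: float = 0.5
    p_family_present: float = 0.5
    abbreviation_rate: float = 0.2
    misspelling_rate: float = 0.1
    systolic_range: tuple[int, int] = (100, 200)
    diastolic_range: tuple[int, int] = (50, 120)
    total_chol_range: tuple[int, int] = (150, 300)
    ldl_range: tuple[int, int] = (60, 160)
    hdl_range: tuple[int, int] = (25, 70)
    tg_range: tuple[int, int] = (80, 300)
    a1c_range: tuple[float, float] = (5.0, 11.0)
    glucose_range: tuple[int, int] = (70, 250)
    bmi_range: tuple[float, float] = (22.0, 42.0)
    # gold-side cutoffs (strict >), mirroring the guideline defaults
    th_systolic: float = 140.0
    th_diastolic: float = 90.0
    th_a1c: float = 6.5
    th_glucose: float = 126.0
    th_total_chol: float = 240.0
    th_ldl: float = 100.0
    th_bmi: float = 30.0
    fh_age_threshold: int = 55

    def __post_init__(self):
        for name, v in vars(self).items():
            if name.startswith("p_") and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("abbreviation_rate", "misspelling_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")


@dataclass(frozen=True)
class PlantedItem:
    start: int
    end: int
    text: str
    risk_factor: str
    indicator: str
    time_class: str | None


@dataclass
class SyntheticNote:
    document: Document
    gold: list[GoldTag]
    planted: list[PlantedItem] = field(default_factory=list)
    sentence_labels: list[tuple[str, str]] = field(default_factory=list)


# --- surface templates -----------------------------------------------------

_DISEASES = [
    # (canonical surface, risk factor, abbreviation, misspelling)
    ("hypertension", "HYPERTENSION", "HTN", "hypertention"),
    ("type 2 diabetes", "DIABETES", "DM2", None),
    ("diabetes", "DIABETES", "DM", "diabetis"),
    ("hyperlipidemia", "HYPERLIPIDEMIA", "HLD", None),
    ("coronary artery disease", "CAD", "CAD", None),
    ("obesity", "OBESITY", None, None),
    ("obese", "OBESITY", None, "obeise"),
]

_MEDS = [
    # (canonical generic, category, abbreviation, misspelling)
    ("lisinopril", "ACE inhibitors", None, "lisinipril"),
    ("losartan", "ARBs", None, None),
    ("aspirin", "aspirin", "ASA", None),
    ("metoprolol", "beta-blockers", None, None),
    ("amlodipine", "calcium-channel blockers", None, None),
    ("sitagliptin", "DPP-4 inhibitors", None, None),
    ("ezetimibe", "ezetimibe", None, None),
    ("gemfibrozil", "fibrates", None, None),
    ("insulin glargine", "insulin", None, None),
    ("metformin", "metformin", None, "metformen"),
    ("niacin", "niacin", None, None),
    ("nitroglycerin", "nitrates", "NTG", None),
    ("pravastatin", "statins", None, "pravastain"),
    ("glipizide", "sulfonylureas", None, None),
    ("hydrochlorothiazide", "thiazide diuretics", "HCTZ", None),
    ("pioglitazone", "thiazolidinediones", None, None),
    ("clopidogrel", "thienopyridines", None, None),
]

_MENTION_TEMPLATES = [  # PAST MEDICAL HISTORY -> continuing
    "History of {d}.",
    "Known {d}.",
    "Longstanding {d}.",
    "{d}, well controlled.",
]
_BEFORE_TEMPLATES = [  # HISTORY OF PRESENT ILLNESS -> before DCT
    "Prior episode of {d} in {year}, now resolved.",
    "Had {d} several years ago.",
    "Remote history of {d}, resolved.",
    "Was treated for {d} in {year}.",
]
_BP_TEMPLATES = [  # VITAL SIGNS -> during DCT
    "BP: {s}/{d}.",
    "Blood pressure {s}/{d}.",
    "Blood pressure elevated at {s}/{d}.",
    "BP {s1}-{s2}/{d1}-{d2} today.",
]
_LIPID_TEMPLATES = [  # LABS -> during DCT
    "Lipid panel: total cholesterol {tc}, TG {tg}, HDL {hdl}, and LDL {ldl}.",
    "Total cholesterol {tc}.",
    "LDL {ldl}, HDL {hdl}.",
    "Cholesterol level {tc}, LDL of {ldl}.",
]
_BLOOD_TEMPLATES = [  # LABS -> during DCT
    "BUN is {bun}, creatinine is {cr}, and glucose is {g}.",
    "Glucose {g}.",
    "A1c {a}.",
    "HbA1c of {a}, glucose {g}.",
]
_BMI_TEMPLATES = [  # VITAL SIGNS -> during DCT
    "BMI {b}.",
    "BMI of {b}.",
    "Body mass index {b}.",
    "BMI: {b}.",
]
_MED_TEMPLATES = [  # MEDICATIONS list -> continuing (section override)
    "{m} {dose} mg daily.",
    "{m} {dose} mg po bid.",
    "{m} {dose} mg qhs.",
    "{m}.",
]
_PLAN_TEMPLATES = [  # PLAN -> after DCT
    "Will start {m} next week.",
    "Plan to start {m} at the next visit.",
    "Start {m} tomorrow.",
    "Consider starting {m} after discharge.",
]
_SMOKING_TEMPLATES = {
    "current": [
        "Patient smokes 1 ppd.",
        "Current smoker, {n} pack years.",
        "He continues to smoke cigarettes daily.",
        "Active tobacco use, {n} packs per year.",
    ],
    "past": [
        "Quit smoking {n} years ago.",
        "Former smoker, quit in {year}.",
        "Past tobacco use, stopped {n} years ago.",
        "Ex-smoker since {year}.",
    ],
    "never": [
        "Never smoked.",
        "Denies tobacco use.",
        "No history of smoking.",
        "Nonsmoker.",
    ],
}
_FH_PRESENT_TEMPLATES = [  # age sampled below the cutoff
    "Father died of CAD at age {a}.",
    "Mother developed coronary artery disease at {a}.",
    "Brother diagnosed with CAD at age {a}, died prematurely.",
    "Father with coronary artery disease, died at age {a}.",
]
_FH_ABSENT_TEMPLATES = [
    "Brother with CAD, died at {a}.",  # age sampled at/above the cutoff
    "Father died of CAD at age {a}.",  # age sampled at/above the cutoff
    "Mother has arthritis.",
    "No family history of premature CAD.",
]
_FILLER = [
    "Patient is doing well.",
    "No acute complaints today.",
    "Follow up in 3 months.",
    "Reviewed diet and exercise.",
    "Return precautions discussed.",
]

_HEADINGS = {
    "chief complaint": ["CHIEF COMPLAINT:", "Chief Complaint:"],
    "history of present illness": ["HISTORY OF PRESENT ILLNESS:", "History of Present Illness:"],
    "past medical history": ["PAST MEDICAL HISTORY:", "Past Medical History:"],
    "medications": ["MEDICATIONS:", "Medications:", "CURRENT MEDICATIONS:"],
    "vital signs": ["VITAL SIGNS:", "Vital Signs:"],
    "labs": ["LABS:", "LABORATORY DATA:"],
    "social history": ["SOCIAL HISTORY:", "Social History:"],
    "family history": ["FAMILY HISTORY:", "Family History:"],
    "plan": ["PLAN:", "Plan:", "ASSESSMENT AND PLAN:"],
}

_ALL3 = tuple(schema.TIME_ATTRS)


class _NoteBuilder:
    def __init__(self) -> None:
        self.lines: list[str] = []
        self.labels: list[str] = []
        self.offset = 0
        self.planted: list[PlantedItem] = []

    def add(self, text: str, label: str = TEXT) -> int:
        start = self.offset
        self.lines.append(text)
        self.labels.append(label)
        self.offset += len(text) + 1
        return start

    def plant(self, line: str, label: str, phrase: str, rf: str, indicator: str,
              time_class: str | None) -> None:
        start = self.add(line, label)
        i = line.lower().index(phrase.lower())
        self.planted.append(
            PlantedItem(start + i, start + i + len(phrase), phrase, rf, indicator, time_class)
        )

    def text(self) -> str:
        return "\n".join(self.lines) + "\n"


def _pick(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


def _disease_surface(rng: np.random.Generator, cfg: GenConfig, entry) -> str:
    surface, _, abbrev, misspell = entry
    if abbrev and rng.random() < cfg.abbreviation_rate:
        return abbrev
    if misspell and rng.random() < cfg.misspelling_rate:
        return misspell
    return surface


def _med_surface(rng: np.random.Generator, cfg: GenConfig, entry) -> str:
    name, _, abbrev, misspell = entry
    if abbrev and rng.random() < cfg.abbreviation_rate:
        return abbrev
    if misspell and rng.random() < cfg.misspelling_rate:
        return misspell
    return name


def _fmt(template: str, **kw) -> str:
    out = template.format(**kw)
    return out[0].upper() + out[1:] if out[:1].islower() else out


def generate_note(rng: np.random.Generator, cfg: GenConfig, doc_id: str,
                  patient_id: str) -> SyntheticNote:
    nb = _NoteBuilder()
    gold: set[tuple[str, str, str | None]] = set()
    year = 2060 + int(rng.integers(0, 15))
    month = 1 + int(rng.integers(0, 12))
    day = 1 + int(rng.integers(0, 28))
    nb.add(f"Record date: {year:04d}-{month:02d}-{day:02d}", SECTION_HEADING_WITH_TEXT)

    def heading(name: str) -> None:
        nb.add(_pick(rng, _HEADINGS[name]), SECTION_HEADING)

    heading("chief complaint")
    nb.add("Follow-up of chronic conditions.")

    # HPI: optional resolved prior episode -> before DCT
    heading("history of present illness")
    nb.add(_pick(rng, _FILLER))
    if rng.random() < cfg.p_disease_before:
        entry = _pick(rng, _DISEASES)
        surface = _disease_surface(rng, cfg, entry)
        line = _fmt(_pick(rng, _BEFORE_TEMPLATES), d=surface, year=year - int(rng.integers(2, 10)))
        nb.plant(line, TEXT, surface, entry[1], "mention", schema.BEFORE_DCT)
        gold.add((entry[1], "mention", schema.BEFORE_DCT))

    # PMH: ongoing disease mentions -> continuing
    heading("past medical history")
    if rng.random() < cfg.p_disease_mention:
        for entry in rng.choice(len(_DISEASES), size=int(rng.integers(1, 4)),
                                replace=False):
            e = _DISEASES[int(entry)]
            surface = _disease_surface(rng, cfg, e)
            line = _fmt(_pick(rng, _MENTION_TEMPLATES), d=surface)
            nb.plant(line, TEXT, surface, e[1], "mention", schema.CONTINUING)
            gold.update((e[1], "mention", t) for t in _ALL3)
    else:
        nb.add("Unremarkable.")

    # MEDICATIONS list -> continuing
    if rng.random() < cfg.p_medication:
        heading("medications")
        for mi in rng.choice(len(_MEDS), size=int(rng.integers(1, 5)), replace=False):
            e = _MEDS[int(mi)]
            surface = _med_surface(rng, cfg, e)
            line = _fmt(_pick(rng, _MED_TEMPLATES), m=surface,
                        dose=int(rng.integers(1, 20)) * 5)
            nb.plant(line, TEXT, surface, schema.MEDICATION, e[1], schema.CONTINUING)
            gold.update((schema.MEDICATION, e[1], t) for t in _ALL3)

    def add_lab_line(line: str, findings: list[tuple[str, str]]) -> None:
        # one planted item per qualifying finding; the evidence span is the
        # whole lab sentence minus its trailing period
        start = nb.add(line)
        end = start + len(line.rstrip("."))
        for rf, indicator in findings:
            gold.add((rf, indicator, schema.DURING_DCT))
            nb.planted.append(
                PlantedItem(start, end, line, rf, indicator, schema.DURING_DCT)
            )

    # VITAL SIGNS: BP and BMI -> during DCT
    want_bp = rng.random() < cfg.p_bp
    want_bmi = rng.random() < cfg.p_bmi
    if want_bp or want_bmi:
        heading("vital signs")
        if want_bp:
            s = int(rng.integers(*cfg.systolic_range))
            d = int(rng.integers(*cfg.diastolic_range))
            t = _pick(rng, _BP_TEMPLATES)
            if "{s1}" in t:
                line = t.format(s1=s - 10, s2=s, d1=d - 4, d2=d)
            else:
                line = t.format(s=s, d=d)
            high = s > cfg.th_systolic or d > cfg.th_diastolic
            add_lab_line(line, [("HYPERTENSION", "high blood pressure")] if high else [])
        if want_bmi:
            b = round(float(rng.uniform(*cfg.bmi_range)), 1)
            line = _pick(rng, _BMI_TEMPLATES).format(b=b)
            add_lab_line(line, [("OBESITY", "BMI")] if b > cfg.th_bmi else [])

    # LABS -> during DCT
    want_lipids = rng.random() < cfg.p_lipids
    want_bloods = rng.random() < cfg.p_bloods
    if want_lipids or want_bloods:
        heading("labs")
        if want_lipids:
            tc = int(rng.integers(*cfg.total_chol_range))
            ldl = int(rng.integers(*cfg.ldl_range))
            line = _pick(rng, _LIPID_TEMPLATES).format(
                tc=tc, ldl=ldl, hdl=int(rng.integers(*cfg.hdl_range)),
                tg=int(rng.integers(*cfg.tg_range)))
            low = line.lower()
            findings = []
            if "cholesterol" in low and tc > cfg.th_total_chol:
                findings.append(("HYPERLIPIDEMIA", "high cholesterol"))
            if "ldl" in low and ldl > cfg.th_ldl:
                findings.append(("HYPERLIPIDEMIA", "high LDL"))
            add_lab_line(line, findings)
        if want_bloods:
            g = int(rng.integers(*cfg.glucose_range))
            a = round(float(rng.uniform(*cfg.a1c_range)), 1)
            line = _pick(rng, _BLOOD_TEMPLATES).format(
                g=g, a=a, bun=int(rng.integers(8, 30)),
                cr=round(float(rng.uniform(0.6, 2.0)), 1))
            low = line.lower()
            findings = []
            if "glucose" in low and g > cfg.th_glucose:
                findings.append(("DIABETES", "high glucose"))
            if "a1c" in low and a > cfg.th_a1c:
                findings.append(("DIABETES", "high A1c"))
            add_lab_line(line, findings)

    # SOCIAL HISTORY: smoking
    smoking_status = "unknown"
    if rng.random() < cfg.p_smoking:
        heading("social history")
        smoking_status = _pick(rng, list(_SMOKING_TEMPLATES))
        line = _pick(rng, _SMOKING_TEMPLATES[smoking_status]).format(
            n=int(rng.integers(2, 30)), year=year - int(rng.integers(2, 20)))
        nb.add(line)
    gold.add((schema.SMOKER, smoking_status, None))

    # FAMILY HISTORY
    family_status = "not present"
    if rng.random() < cfg.p_family_history:
        heading("family history")
        if rng.random() < cfg.p_family_present:
            family_status = "present"
            a = int(rng.integers(35, cfg.fh_age_threshold))
            line = _pick(rng, _FH_PRESENT_TEMPLATES).format(a=a)
        else:
            a = int(rng.integers(cfg.fh_age_threshold, 90))
            line = _pick(rng, _FH_ABSENT_TEMPLATES).format(a=a)
        nb.add(line)
        if "cad" in line.lower() or "coronary artery disease" in line.lower():
            # the CAD surface inside the family-history sentence is itself a
            # recognizable mention; gold accounts for it as continuing
            phrase = "coronary artery disease" if "coronary artery disease" in line.lower() else "CAD"
            i = line.lower().index(phrase.lower())
            start = nb.offset - len(line) - 1
            nb.planted.append(PlantedItem(start + i, start + i + len(phrase), phrase,
                                          "CAD", "mention", schema.CONTINUING))
            gold.update(("CAD", "mention", t) for t in _ALL3)
    gold.add((schema.FAMILY_HIST, family_status, None))

    # PLAN: future medication -> after DCT
    heading("plan")
    nb.add(_pick(rng, _FILLER))
    if rng.random() < cfg.p_plan_med:
        e = _pick(rng, _MEDS)
        line = _fmt(_pick(rng, _PLAN_TEMPLATES), m=e[0])
        nb.plant(line, TEXT, e[0], schema.MEDICATION, e[1], schema.AFTER_DCT)
        gold.add((schema.MEDICATION, e[1], schema.AFTER_DCT))

    doc = Document.from_text(doc_id, nb.text(), patient_id=patient_id)
    tags = sorted(GoldTag(doc_id, rf, ind, t) for rf, ind, t in gold)
    return SyntheticNote(doc, tags, nb.planted,
                         list(zip(nb.lines, nb.labels)))


def generate_notes(cfg: GenConfig) -> list[SyntheticNote]:
    rng = np.random.default_rng(cfg.seed)
    notes = []
    for p in range(cfg.n_patients):
        for n in range(cfg.notes_per_patient):
            doc_id = f"P{p:03d}-{n:02d}"
            notes.append(generate_note(rng, cfg, doc_id, f"P{p:03d}"))
    return notes


def generate_corpus(cfg: GenConfig) -> list[tuple[Document, list[GoldTag]]]:
    """The public corpus view: (document, gold tags) pairs, seeded."""
    return [(n.document, n.gold) for n in generate_notes(cfg)]


def write_corpus(notes: list[SyntheticNote], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for note in notes:
        path = out_dir / f"{note.document.doc_id}.xml"
        write_annotations(note.document, note.gold, path)
        paths.append(path)
    return paths


# --- training material -----------------------------------------------------

def sectionizer_training(notes: list[SyntheticNote]) -> list[list[tuple[str, str]]]:
    """Per-note (sentence text, section label) sequences.

    Sentence texts come from the real sentence splitter so training input
    matches extraction-time input exactly; labels come from the builder.
    """
    out = []
    for note in notes:
        sents = core_nlp.split_sentences(note.document.text)
        labels = [lab for line, lab in note.sentence_labels if line.strip()]
        assert len(sents) == len(labels), note.document.doc_id
        out.append([(s.text, l) for s, l in zip(sents, labels)])
    return out


def smoking_training(cfg: GenConfig, per_class: int = 120) -> list[tuple[str, str]]:
    """Labeled smoking sentences, ``per_class`` of each status class."""
    rng = np.random.default_rng(cfg.seed + 1)
    out = []
    for cls, templates in _SMOKING_TEMPLATES.items():
        for _ in range(per_class):
            line = _pick(rng, templates).format(
                n=int(rng.integers(2, 30)), year=int(rng.integers(2040, 2070)))
            out.append((line, cls))
    order = rng.permutation(len(out))
    return [out[int(i)] for i in order]


def time_training(notes: list[SyntheticNote]) -> list[tuple[TimeFeatureVector, str]]:
    """(feature vector, time class) pairs for every planted timed item.

    Features are computed with the pipeline's own featurizer over gold
    section labels; the class labels come from the planting templates.
    """
    out = []
    for note in notes:
        processed = core_nlp.process(note.document)
        labels = [lab for line, lab in note.sentence_labels if line.strip()]
        sectioned = [SectionedSentence(ps.sentence, lab)
                     for ps, lab in zip(processed, labels)]
        from .sectionizer import _propagate_names  # gold-label propagation

        _propagate_names(sectioned)
        for item in note.planted:
            if item.time_class is None or item.start == item.end:
                continue
            ctx = [(ps, ss) for ps, ss in zip(processed, sectioned)
                   if ps.sentence.start <= item.start < ps.sentence.end]
            if not ctx:
                continue
            ps, ss = ctx[0]
            fv = featurize_time((item.start, item.end), item.indicator, ps, ss)
            out.append((fv, item.time_class))
    return out
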