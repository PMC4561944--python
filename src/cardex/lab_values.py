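"""Pattern-based extraction of lab values and threshold filtering.

Recognized kinds: blood pressure (systolic/diastolic, mmHg), lipid panel
(total cholesterol, TG, HDL, LDL, mg/dL), blood tests (BUN, creatinine,
glucose, mg/dL; A1c, %), and BMI (kg/m²).  Patterns operate on raw sentence
text.  Range expressions like "120-130/88-92" store the per-component
maximum, so a transiently high reading is never hidden by the low end of
the range.

Threshold filtering turns values into risk-factor evidence with strict
inequalities: blood pressure qualifies as hypertension when systolic > 140
or diastolic > 90; the remaining cutoffs default to standard clinical
guideline values and are configurable.  BUN, creatinine, and TG are
extracted but never promoted to a risk factor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


@dataclass(frozen=True)
class LabValue:
    kind: str  # BP, TOTAL_CHOL, TG, HDL, LDL, A1C, GLUCOSE, BMI, BUN, CREATININE
    value: float  # for BP: systolic
    value2: float | None  # for BP: diastolic
    units: str
    start: int
    end: int

    @property
    def systolic(self) -> float:
        assert self.kind == "BP"
        return self.value

    @property
    def diastolic(self) -> float:
        assert self.kind == "BP"
        assert self.value2 is not None
        return self.value2


@dataclass
class Thresholds:
    """Cutoffs above which a value is risk-factor evidence (strict >)."""

    systolic_high: float = 140.0
    diastolic_high: float = 90.0
    a1c_high: float = 6.5
    glucose_high: float = 126.0
    total_chol_high: float = 240.0
    ldl_high: float = 100.0
    bmi_obese: float = 30.0

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v <= 0:
                raise ValueError(f"threshold {name} must be positive, got {v}")


_NUM = r"\d{1,3}(?:\.\d+)?"
# one BP component: a number or a number range ("120-130", en dash or hyphen)
_COMP = rf"({_NUM})(?:\s*[-–—]\s*({_NUM}))?"
_BP_RE = re.compile(
    rf"(?:\bBP\s*:?\s*|\bblood\s+pressure\s+(?:\w+\s+){{0,3}}?(?:at\s+)?|(?<![\d/.\-]))"
    rf"{_COMP}\s*/\s*{_COMP}(?!\d|\.\d|/)",
    re.IGNORECASE,
)
_BP_CUE_RE = re.compile(r"\bBP\b|\bblood\s+pressure\b", re.IGNORECASE)


def _comp_max(a: str, b: str | None) -> float:
    return max(float(a), float(b)) if b else float(a)


def extract_blood_pressure(text: str, offset: int = 0) -> list[LabValue]:
    """Blood-pressure readings from one sentence.

    Handles the dialects "BP: 158/72", "blood pressure 149/96",
    "blood pressure elevated at 188/92", and ranges "120-130/88-92"
    (per-component maximum).  A sentence must carry a BP cue word; the
    systolic/diastolic plausibility gate is 50-300 / 30-200.
    """
    if not _BP_CUE_RE.search(text):
        return []
    values = []
    for m in _BP_RE.finditer(text):
        s = _comp_max(m.group(1), m.group(2))
        d = _comp_max(m.group(3), m.group(4))
        if 50 <= s <= 300 and 30 <= d <= 200:
            values.append(LabValue("BP", s, d, "mmHg", offset + m.start(), offset + m.end()))
    return values


_LIPID_KINDS = [
    ("TOTAL_CHOL", r"total\s+cholesterol|cholesterol"),
    ("TG", r"TG|triglycerides?"),
    ("HDL", r"HDL"),
    ("LDL", r"LDL"),
]
_MISC_KINDS = [
    ("A1C", r"HbA1c|hemoglobin\s+A1c|A1c"),
    ("GLUCOSE", r"glucose|blood\s+sugar"),
    ("BUN", r"BUN"),
    ("CREATININE", r"creatinine"),
]
_UNITS = {
    "TOTAL_CHOL": "mg/dL", "TG": "mg/dL", "HDL": "mg/dL", "LDL": "mg/dL",
    "A1C": "%", "GLUCOSE": "mg/dL", "BUN": "mg/dL", "CREATININE": "mg/dL",
    "BMI": "kg/m2",
}
_JOIN = r"(?:\s+(?:is|was|of|level|count|elevated|high|low))*\s*(?:at\s+|:\s*)?"


def _keyword_number(text: str, offset: int, kinds: list[tuple[str, str]]) -> list[LabValue]:
    out = []
    taken: list[tuple[int, int]] = []
    for kind, kw in kinds:
        pat = re.compile(
            rf"(?<![A-Za-z])(?:{kw}){_JOIN}(\d+(?:\.\d+)?)(?!\d*\s*/)", re.IGNORECASE
        )
        for m in pat.finditer(text):
            span = (m.start(), m.end())
            if any(span[0] < e and s < span[1] for s, e in taken):
                continue
            taken.append(span)
            out.append(
                LabValue(kind, float(m.group(1)), None, _UNITS[kind],
                         offset + span[0], offset + span[1])
            )
    return sorted(out, key=lambda v: v.start)


def extract_lipids(text: str, offset: int = 0) -> list[LabValue]:
    """Lipid-panel values: one LabValue per analyte keyword followed by a number."""
    return _keyword_number(text, offset, _LIPID_KINDS)


def extract_misc_bloods(text: str, offset: int = 0) -> list[LabValue]:
    """Blood-test values: A1c, glucose, BUN, creatinine."""
    return _keyword_number(text, offset, _MISC_KINDS)


def extract_bmi(text: str, offset: int = 0) -> list[LabValue]:
    """Body-mass-index values ("BMI 32", "BMI of 34.5")."""
    return _keyword_number(text, offset, [("BMI", r"BMI|body\s+mass\s+index")])


def extract_all(text: str, offset: int = 0) -> list[LabValue]:
    """Every lab value in one sentence, in left-to-right span order."""
    values = extract_blood_pressure(text, offset)
    bp_spans = [(v.start, v.end) for v in values]
    for v in extract_lipids(text, offset) + extract_misc_bloods(text, offset) + extract_bmi(text, offset):
        if not any(v.start < e and s < v.end for s, e in bp_spans):
            values.append(v)
    return sorted(values, key=lambda v: (v.start, v.kind))


# kind -> (risk factor, indicator, predicate name)
_PROMOTIONS = {
    "A1C": ("DIABETES", "high A1c", "a1c_high"),
    "GLUCOSE": ("DIABETES", "high glucose", "glucose_high"),
    "TOTAL_CHOL": ("HYPERLIPIDEMIA", "high cholesterol", "total_chol_high"),
    "LDL": ("HYPERLIPIDEMIA", "high LDL", "ldl_high"),
    "BMI": ("OBESITY", "BMI", "bmi_obese"),
}


def filter_by_threshold(
    values: list[LabValue], th: Thresholds | None = None
) -> list[tuple[LabValue, str, str]]:
    """Keep values that qualify as risk-factor evidence.

    Returns (value, risk_factor, indicator) triples.  Non-qualifying values
    and kinds with no associated risk factor (BUN, creatinine, TG, HDL)
    are dropped.
    """
    th = th or Thresholds()
    kept = []
    for v in values:
        if v.kind == "BP":
            if v.systolic > th.systolic_high or v.diastolic > th.diastolic_high:
                kept.append((v, "HYPERTENSION", "high blood pressure"))
        elif v.kind in _PROMOTIONS:
            rf, indicator, attr = _PROMOTIONS[v.kind]
            if v.value > getattr(th, attr):
                kept.append((v, rf, indicator))
    return kept
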