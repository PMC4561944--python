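"""Tag schema: risk factors, their legal indicator attributes, and time attributes.

Every annotation the pipeline emits is validated against this machine-readable
schema.  Indicators are the evidence type behind a risk-factor tag (a textual
mention, a lab value over threshold, a medication category, a document-level
status); time attributes locate the evidence relative to the document creation
time (DCT).
"""

from __future__ import annotations

BEFORE_DCT = "before DCT"
DURING_DCT = "during DCT"
AFTER_DCT = "after DCT"
CONTINUING = "continuing"  # classifier class only, never a stored attribute

TIME_ATTRS = (BEFORE_DCT, DURING_DCT, AFTER_DCT)
TIME_CLASSES = (BEFORE_DCT, DURING_DCT, AFTER_DCT, CONTINUING)

CAD = "CAD"
DIABETES = "DIABETES"
FAMILY_HIST = "FAMILY_HIST"
HYPERLIPIDEMIA = "HYPERLIPIDEMIA"
HYPERTENSION = "HYPERTENSION"
MEDICATION = "MEDICATION"
OBESITY = "OBESITY"
SMOKER = "SMOKER"

RISK_FACTORS = (
    CAD,
    DIABETES,
    FAMILY_HIST,
    HYPERLIPIDEMIA,
    HYPERTENSION,
    MEDICATION,
    OBESITY,
    SMOKER,
)

# Medication indicator values are the heart-disease-related drug categories.
MEDICATION_CATEGORIES = (
    "ACE inhibitors",
    "ARBs",
    "amylin",
    "antidiabetes medications",
    "aspirin",
    "beta-blockers",
    "calcium-channel blockers",
    "DPP-4 inhibitors",
    "ezetimibe",
    "fibrates",
    "GLP-1 agonists",
    "insulin",
    "meglitinides",
    "metformin",
    "niacin",
    "nitrates",
    "obesity",
    "statins",
    "sulfonylureas",
    "thiazide diuretics",
    "thiazolidinediones",
    "thienopyridines",
)

LEGAL_INDICATORS: dict[str, tuple[str, ...]] = {
    CAD: ("mention", "event", "test result", "symptom"),
    DIABETES: ("mention", "high A1c", "high glucose"),
    FAMILY_HIST: ("present", "not present"),
    HYPERLIPIDEMIA: ("mention", "high cholesterol", "high LDL"),
    HYPERTENSION: ("mention", "high blood pressure"),
    MEDICATION: MEDICATION_CATEGORIES,
    OBESITY: ("mention", "BMI", "waist circumference"),
    SMOKER: ("current", "past", "never", "unknown"),
}

# Risk factors whose tag is document-level and carries no time attribute.
TIMELESS = (FAMILY_HIST, SMOKER)


def is_legal(risk_factor: str, indicator: str, time_attr: str | None = None) -> bool:
    """True when (risk_factor, indicator, time_attr) is a legal tag triple."""
    if risk_factor not in LEGAL_INDICATORS:
        return False
    if indicator not in LEGAL_INDICATORS[risk_factor]:
        return False
    if risk_factor in TIMELESS:
        return time_attr is None
    return time_attr is None or time_attr in TIME_ATTRS


def validate(risk_factor: str, indicator: str, time_attr: str | None = None) -> None:
    """Raise ``ValueError`` for an illegal tag triple."""
    if not is_legal(risk_factor, indicator, time_attr):
        raise ValueError(
            f"illegal tag: risk_factor={risk_factor!r} indicator={indicator!r} "
            f"time={time_attr!r}"
        )
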