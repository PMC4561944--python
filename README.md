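# cardex

Hybrid rule + machine-learning extraction of **heart-disease risk factors**
from longitudinal clinical notes of diabetic patients.

Risk assessment for heart disease needs structured risk-factor data —
diabetes, coronary artery disease (CAD), hypertension, hyperlipidemia,
obesity, cardiac medications, smoking history, and family history of
premature CAD — but in electronic health records most of that evidence is
buried in free-text notes. `cardex` turns a plain-text note into a set of
document-level tags, each a triple

    (risk factor, indicator attribute, time attribute)

where the *indicator* says what kind of evidence supports the tag (a textual
mention, a lab value over a guideline cutoff, a medication category, a CAD
event/test/symptom, or a document-level status) and the *time attribute*
locates the evidence relative to the note's **document creation time (DCT)**:
before DCT, during DCT, and/or after DCT. Smoking status and family history
are document-level tags with no time attribute.

## How it works

1. **Core NLP** — rule-based sentence detection (newlines are hard
   boundaries, so headings like `MEDICATIONS:` are isolated), tokenization,
   a deterministic lexicon/suffix POS tagger, and noun-phrase chunking.
2. **Recognition** — dictionary matching for disease mentions (with
   abbreviation expansion: `DM2` → diabetes type 2, `HTN` → hypertension,
   and a misspelling map: `pravastain` → pravastatin) and for medication
   generics mapped to 21 heart-disease drug categories; regular-expression
   extraction of lab values (blood-pressure dialects `BP: 158/72`,
   `blood pressure elevated at 188/92`, ranges `120–130/88–92` taken at the
   per-component maximum; lipid panel; A1c/glucose/BUN/creatinine; BMI)
   filtered by strict guideline thresholds, e.g. hypertension when
   systolic > 140 or diastolic > 90 mmHg.
3. **Section segmentation** — a linear-chain CRF labels each sentence as a
   section heading, a heading-with-text, or text, with a dictionary
   override; the prevailing section name is a key feature downstream.
4. **Document classifiers** — sentence-level multinomial Naive Bayes for
   smoking status (current/past/never, resolved per document with priority
   current > past > never, "unknown" when no smoking term occurs) and rules
   for family history of premature CAD (CAD term + first-degree relative +
   age below a configurable cutoff, default 55).
5. **Attribute assignment** — a declarative rule ledger maps each recognized
   item to its indicator; a 4-class Naive Bayes (before/during/after DCT or
   *continuing*) assigns time, with "continuing" expanded to all three
   attributes and medication lists under a medications heading always
   continuing.

Because the corpora such systems are built on are access-restricted, the
package ships a seeded **synthetic-note generator** that plants all of these
constructs with known gold tags, plus a tag-level **evaluator**
(micro/macroaveraged precision, recall, F-score by risk factor, indicator,
and time attribute). The learned components train on generated material, so
the whole pipeline runs end to end with no external data.

## Worked example

```python
from cardex import Document, GenConfig, train_pipeline
from cardex.synthetic_data import (generate_notes, sectionizer_training,
                                   smoking_training, time_training)

cfg = GenConfig(seed=11, n_patients=40, notes_per_patient=3)
notes = generate_notes(cfg)
pipe = train_pipeline(sectionizer_training(notes), smoking_training(cfg),
                      time_training(notes), seed=11)

note = """Record date: 2073-12-14
PAST MEDICAL HISTORY:
History of HTN.
MEDICATIONS:
ASA 81 mg daily.
VITAL SIGNS:
BP: 158/72.
SOCIAL HISTORY:
Quit smoking 10 years ago.
FAMILY HISTORY:
Father died of CAD at age 50.
"""
doc = Document.from_text("note-1", note)
for a in pipe.extract(doc):
    print(f"{a.risk_factor:<13} {a.indicator:<20} {sorted(a.time_attrs)}")
```

prints

```
CAD           mention              ['after DCT', 'before DCT', 'during DCT']
FAMILY_HIST   present              []
HYPERTENSION  high blood pressure  ['during DCT']
HYPERTENSION  mention              ['after DCT', 'before DCT', 'during DCT']
MEDICATION    aspirin              ['after DCT', 'before DCT', 'during DCT']
SMOKER        past                 []
```

Reading the output: `HTN` expanded to a hypertension *mention* classified as
an ongoing condition (all three time attributes); the reading 158/72 exceeds
the systolic cutoff, so it is separate *high blood pressure* evidence tied to
the visit (during DCT); `ASA` resolved to the aspirin category on a
medication list (always all three times); the father's CAD death at 50 (< 55)
makes family history *present*; and "quit smoking" yields smoking status
*past*.

The same workflow is available from the shell:

```sh
cardex simulate --seed 5  --out corpus/
cardex train    --seed 11 --out models/
cardex extract  --input corpus/ --models models/ --out pred/
cardex evaluate --gold corpus/ --pred pred/ --out report
```

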