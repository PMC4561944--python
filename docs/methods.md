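# Methods

## Task and tag schema

The system emits document-level tags `(risk factor, indicator attribute,
time attribute)` for eight heart-disease risk factors: CAD, diabetes,
hyperlipidemia, hypertension, obesity, medication use, smoking history, and
family history of premature CAD. Legal indicator values per risk factor are
encoded in `cardex.schema` (e.g. diabetes: mention / high A1c / high
glucose; hypertension: mention / high blood pressure; medication: one of the
heart-disease drug categories). Time attributes — before, during, after the
document creation time (DCT) — apply to all risk factors except smoking and
family history, which are document-level statuses. *Continuing* is a
classifier class only; it is always expanded to all three stored time
attributes.

The drug-category enumeration deserves a note: the category list printed in
the source material counts 21 categories in prose but enumerates 22 values.
The schema accepts all 22; the shipped starter dictionary populates 21 of
them (the "obesity" medication category is left empty — obesity-drug
mentions are vanishingly rare in this document genre), with roughly 85
generics total. The dictionary is a TSV and fully overridable; the method is
the dictionary-plus-rules mechanism, not any particular drug list.

## Core NLP

Clinical notes are line-oriented, so newlines are hard sentence boundaries —
this isolates headings, which the sectionizer classifies per sentence — and
full stops split within lines (decimals like `4.7` never split because the
period is not followed by whitespace). Offsets are 0-based half-open
character intervals into the raw text, so every sentence and token
round-trips exactly (`text[start:end] == surface`).

POS tagging is a deterministic lexicon + suffix tagger emitting Penn-style
tags. Downstream consumers only rely on the coarse noun/verb/number
distinction (chunk boundaries, feature strings), so a full statistical
tagger would add a dependency without changing behavior; the contract is the
module interface, and any tagger honoring it can be swapped in. Noun-phrase
chunks are maximal runs of determiner/adjective/number/noun tokens
containing a noun.

## Lexicons and recognition

Seven lexicon files (TSV maps / term lists) drive recognition: disease
terms → risk factor, abbreviation → long form, medication generic →
category, smoking terms, section headings, family-relation terms, and a
misspelling map. Abbreviation expansion is exact-match and runs before
misspelling correction; both are idempotent (validated at load: the
abbreviation map must be acyclic). There is deliberately no fuzzy matching —
only the explicit misspelling map — since generic spelling correction is a
separate problem.

Disease and medication matching runs over raw sentence text with
word-boundary anchoring, case-insensitive, longest-alternative-first;
overlapping matches of the same risk factor collapse to the longest.
Abbreviations and misspellings are folded into the surface index so `HTN`
and `hypertension` behave identically. CAD event / test-result / symptom
phrases come from small starter lexicons and are the known-weak component:
the phrase inventory of real notes is far richer than any starter list.

## Lab values and thresholds

Regular expressions extract blood pressure (dialects `BP: S/D`,
`blood pressure S/D`, `blood pressure <words> at S/D`, and ranges
`S1–S2/D1–D2`), the lipid panel, blood tests (A1c, glucose, BUN,
creatinine), and BMI. Range expressions store the **per-component maximum**:
a transiently high reading should trigger the threshold check, and taking
the low end is precisely the failure mode a range-naive extractor exhibits.
A plausibility gate (systolic 50–300, diastolic 30–200 mmHg) rejects
spurious slash-number matches; a BP cue word (`BP` / `blood pressure`) must
occur in the sentence.

Threshold filtering uses strict inequalities. Blood pressure qualifies as
hypertension evidence when systolic > 140 **or** diastolic > 90 mmHg. The
remaining cutoffs are the standard clinical guideline values — A1c > 6.5 %,
glucose > 126 mg/dL, total cholesterol > 240 mg/dL, LDL > 100 mg/dL,
BMI > 30 kg/m² — all configurable (`Thresholds`); they are stated
assumptions, not derived facts. BUN, creatinine, TG, and HDL are extracted
but never promoted to risk-factor evidence. No unit conversion is attempted
(mg/dL is assumed for blood chemistry).

## Sectionizer

A linear-chain CRF labels each sentence SECTION_HEADING,
SECTION_HEADING_WITH_TEXT, or TEXT. The chain structure was chosen because
the feature template includes the previous and next sentences' features —
sequential dependence is already baked into the design. Features per
sentence: first-word uppercased, all-words uppercased/lowercased, heading
dictionary match, first word, second word, trailing full stop, colon
presence, plus both neighbors' own local features (non-recursive) and
boundary markers. The CRF is trained by penalized maximum likelihood
(L2, c2 = 0.1, L-BFGS, ≤ 150 iterations) with exact forward-backward
gradients and Viterbi decoding; training is deterministic given the data
order (features indexed in sorted order, zero initialization). After
decoding, a rule relabels TEXT sentences that are verbatim heading-lexicon
terms, and the prevailing section name (text before the first colon,
lower-cased) propagates forward.

## Smoking and family history

Smoking is classified per sentence (multinomial Naive Bayes, additive
smoothing α = 1, features: bag of lower-cased words + POS tags) over
sentences containing a smoking-lexicon term, then resolved per document by
the priority **current > past > never** — a current-smoker statement
dominates on clinical-recency grounds. No smoking sentence ⇒ "unknown".
The "ever" status is excluded from the class set entirely. Naive Bayes
posterior ties break by the fixed class order (current, past, never) after
rounding log-posteriors to 12 decimals, making prediction deterministic.

Family history of premature CAD is rule-based: a single sentence must
contain a CAD term, a first-degree-relative term (father/mother/brother
extended with sister/parent/sibling/dad/mom), and a parseable age below the
premature cutoff in patterns like "at age N", "aged N", "died … N",
"N years old". The cutoff defaults to **55 years** and is configurable
(`--fh-age-threshold`); the literature uses both 55 and 45 depending on sex
and guideline. A CAD+relative sentence with no parseable age is treated as
not premature. The outcome maps onto the two-valued tag present /
not present.

## Time attributes

Each recognized item is featurized as: its span tokens, previous word and
POS, next word and POS (sentinel `<none>` at boundaries), the prevailing
section name, and the indicator attribute. A 4-class multinomial Naive
Bayes picks before / during / after DCT or continuing (ties break in that
fixed order); *continuing* expands to all three attributes. One
deterministic override is applied after the classifier: medication mentions
whose section name is a medication-list heading are always continuing —
drug lists enumerate ongoing therapy. Annotations with identical
(risk factor, indicator, time set) merge, unioning evidence spans.

## Evaluation

Matching is tag-level per document, not span-level: the deliverable of the
task is the document's risk-factor profile, and smoking/family history are
inherently document-level. A 3-time annotation expands to three countable
tags. Micro scores pool TP/FP/FN over documents; macro scores average
per-document P/R/F with equal document weight. When a document has neither
gold nor predicted tags for a scoring key it is skipped for that key by
default; the alternative convention (count as zeros) is available as
`empty_empty="zero"` because evaluation scripts in this area differ on
exactly this point, and with sparse per-key tags the choice moves macro
averages substantially.

## Synthetic corpus

The generator emulates the *structure* this pipeline consumes, not clinical
language: a record-date header, 5–9 headed sections, and planted constructs,
each with ≥ 4 surface dialects (including every documented BP phrasing and
the range form). Defaults: 10 patients × 3 notes; inclusion probabilities
per note — BP 0.5, lipids 0.4, bloods 0.4, BMI 0.3, ongoing disease
mentions 0.8, resolved prior episode 0.3, medication list 0.8, planned
future medication 0.3, smoking 0.7, family history 0.5 (present half the
time); abbreviation rate 0.2 and misspelling rate 0.1 on surfaces that have
them; lab values uniform over ranges wide enough to straddle the cutoffs
(systolic 100–200, diastolic 50–120, total cholesterol 150–300, LDL 60–160,
A1c 5–11, glucose 70–250, BMI 22–42). These are one-time choices meant to
look like a mixed primary-care panel while exercising both branches of every
threshold.

Gold tags come from the planting decisions via the generator's own inline
threshold arithmetic — it shares no code with the extractor, so end-to-end
agreement is a genuine two-implementation check. Time-attribute gold follows
the construct templates: ongoing conditions and medication lists are
continuing, resolved prior episodes are before DCT, measured lab values are
during DCT, planned medications are after DCT, and a CAD surface inside a
family-history sentence is additionally gold-tagged as a continuing CAD
mention (the recognizer will legitimately find it). Training material for
the three learned components is emitted from the same templates, which makes
the classes separable by construction.

What passing on this corpus shows: the rules cover the planted dialects, the
learned components recover template-governed structure, and the plumbing
(offsets, merging, expansion, I/O, scoring) is sound. What it does not show:
performance on real clinical prose — narrative variation, negation, section
vocabularies, and abbreviation inventories far exceed the templates, and
scores on restricted shared-task corpora are substantially lower than the
near-perfect recovery seen here.

## Numerical and determinism notes

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; generation, training, and evaluation are
  bit-reproducible (models expose a SHA-256 `model_hash` over rounded
  weights).
- Strict inequalities everywhere a cutoff is applied; boundary values
  (exactly 140/90, exactly 6.5 %) do **not** qualify.
- Degenerate inputs: empty text yields no sentences; empty lexicon files
  yield a valid no-match pipeline; training aborts with a named-class error
  if any class is absent; a heading with no colon falls back to its whole
  text as the section name (with a warning).
- Problem sizes in the shipped tests: training on 120 generated notes
  (40 patients × 3), end-to-end scoring on a fresh 200-note corpus,
  held-out classifier checks on 30 notes and 150 sentences — small enough to
  run in well under a minute while covering every template dialect.

## Known limitations

- No negation or assertion handling: "no CAD" still yields a CAD mention.
- CAD event/test/symptom lexicons are minimal starters.
- One note per file; multi-record longitudinal files are not delimited.
- No unit conversion; mmol/L values would be misread as qualifying or not
  against mg/dL cutoffs.
- Waist circumference is not extracted.
- The evaluator is a reimplementation of the tag-level protocol, not a
  byte-for-byte port of any shared-task script.
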