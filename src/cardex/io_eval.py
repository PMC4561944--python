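"""Corpus I/O in an XML dialect and micro/macro P-R-F evaluation.

A corpus is a directory of one XML file per note: a ``TEXT`` element holding
the raw note verbatim and a ``TAGS`` element of empty ``TAG`` elements with
``risk_factor``, ``indicator`` and (except for smoking and family history)
``time`` attributes.  Matching is tag-level per document — (risk factor,
indicator, time attribute) — not span-level; an annotation spanning three
time attributes expands to three tags.

Microaveraging pools TP/FP/FN over all documents; macroaveraging is the
unweighted mean of per-document precision/recall/F.  Documents with neither
gold nor predicted tags for a scoring key are skipped for that key by
default, or counted as zeros (``empty_empty="zero"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from . import schema
from .attribute_assignment import RiskFactorAnnotation
from .core_nlp import Document


@dataclass(frozen=True, order=True)
class GoldTag:
    doc_id: str
    risk_factor: str
    indicator: str
    time_attr: str | None  # None for SMOKER / FAMILY_HIST

    def __post_init__(self):
        schema.validate(self.risk_factor, self.indicator, self.time_attr)


class CorpusError(ValueError):
    pass


def read_document(path: str | Path) -> tuple[Document, list[GoldTag]]:
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    doc_id = root.get("id") or path.stem
    text_el = root.find("TEXT")
    text = text_el.text or "" if text_el is not None else ""
    doc = Document.from_text(doc_id, text, patient_id=root.get("patient_id", ""))
    tags = []
    tags_el = root.find("TAGS")
    if tags_el is not None:
        for el in tags_el.findall("TAG"):
            try:
                tags.append(
                    GoldTag(doc_id, el.get("risk_factor"), el.get("indicator"),
                            el.get("time"))
                )
            except ValueError as exc:
                raise CorpusError(f"{path}:{el.sourceline}: {exc}") from exc
    return doc, tags


def read_corpus(path: str | Path) -> list[tuple[Document, list[GoldTag]]]:
    """Read every ``*.xml`` under a directory (sorted), or one file."""
    path = Path(path)
    files = sorted(path.glob("*.xml")) if path.is_dir() else [path]
    if not files:
        raise CorpusError(f"no XML documents under {path}")
    return [read_document(f) for f in files]


def annotation_tags(doc_id: str, annotations: list[RiskFactorAnnotation]) -> list[GoldTag]:
    """Expand annotations to per-time gold tags (the evaluation unit)."""
    tags = []
    for a in annotations:
        if a.risk_factor in schema.TIMELESS:
            tags.append(GoldTag(doc_id, a.risk_factor, a.indicator, None))
        else:
            for t in sorted(a.time_attrs):
                tags.append(GoldTag(doc_id, a.risk_factor, a.indicator, t))
    return sorted(set(tags))


def write_annotations(
    doc: Document, annotations: list[RiskFactorAnnotation] | list[GoldTag], path: str | Path
) -> None:
    """Write one document with its tags; round-trips through read_document."""
    root = etree.Element("doc", id=doc.doc_id)
    if doc.patient_id:
        root.set("patient_id", doc.patient_id)
    text_el = etree.SubElement(root, "TEXT")
    text_el.text = etree.CDATA(doc.text)
    tags_el = etree.SubElement(root, "TAGS")
    if annotations and isinstance(annotations[0], RiskFactorAnnotation):
        tags = annotation_tags(doc.doc_id, annotations)
    else:
        tags = sorted(set(annotations))
    for t in tags:
        el = etree.SubElement(tags_el, "TAG", risk_factor=t.risk_factor,
                              indicator=t.indicator)
        if t.time_attr is not None:
            el.set("time", t.time_attr)
    etree.ElementTree(root).write(str(path), encoding="utf-8",
                                  xml_declaration=True, pretty_print=True)


# --- evaluation ------------------------------------------------------------

Key = tuple[str, str, str | None]  # (risk_factor, indicator, time)


@dataclass
class Scores:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    micro_p: float = 0.0
    micro_r: float = 0.0
    micro_f: float = 0.0
    macro_p: float = 0.0
    macro_r: float = 0.0
    macro_f: float = 0.0


@dataclass
class EvalReport:
    overall: Scores
    by_risk_factor: dict[str, Scores] = field(default_factory=dict)
    by_indicator: dict[tuple[str, str], Scores] = field(default_factory=dict)
    by_time: dict[tuple[str, str], Scores] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def enc(s: Scores) -> dict:
            return {k: getattr(s, k) for k in vars(s)}

        return {
            "overall": enc(self.overall),
            "by_risk_factor": {k: enc(v) for k, v in self.by_risk_factor.items()},
            "by_indicator": {f"{rf}|{ind}": enc(v) for (rf, ind), v in self.by_indicator.items()},
            "by_time": {f"{rf}|{t}": enc(v) for (rf, t), v in self.by_time.items()},
        }

    def to_tsv(self) -> str:
        lines = ["level\tkey\tmacro_p\tmacro_r\tmacro_f\tmicro_p\tmicro_r\tmicro_f"]

        def row(level: str, key: str, s: Scores) -> str:
            return (f"{level}\t{key}\t{s.macro_p:.4f}\t{s.macro_r:.4f}\t{s.macro_f:.4f}"
                    f"\t{s.micro_p:.4f}\t{s.micro_r:.4f}\t{s.micro_f:.4f}")

        for rf, s in sorted(self.by_risk_factor.items()):
            lines.append(row("risk_factor", rf, s))
        for (rf, ind), s in sorted(self.by_indicator.items()):
            lines.append(row("indicator", f"{rf}/{ind}", s))
        for (rf, t), s in sorted(self.by_time.items()):
            lines.append(row("time", f"{rf}/{t}", s))
        lines.append(row("overall", "all", self.overall))
        return "\n".join(lines) + "\n"


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def _score(gold: dict[str, set[Key]], pred: dict[str, set[Key]],
           empty_empty: str) -> Scores:
    s = Scores()
    per_doc: list[tuple[float, float, float]] = []
    for doc_id in gold:
        g, p = gold[doc_id], pred.get(doc_id, set())
        tp, fp, fn = len(g & p), len(p - g), len(g - p)
        s.tp += tp
        s.fp += fp
        s.fn += fn
        if not g and not p:
            if empty_empty == "skip":
                continue
            per_doc.append((0.0, 0.0, 0.0))
        else:
            per_doc.append(_prf(tp, fp, fn))
    s.micro_p, s.micro_r, s.micro_f = _prf(s.tp, s.fp, s.fn)
    if per_doc:
        n = len(per_doc)
        s.macro_p = sum(x[0] for x in per_doc) / n
        s.macro_r = sum(x[1] for x in per_doc) / n
        s.macro_f = sum(x[2] for x in per_doc) / n
    return s


def evaluate(
    gold: list[GoldTag], predicted: list[GoldTag], empty_empty: str = "skip"
) -> EvalReport:
    """Score predicted tags against gold at every reporting level.

    The predicted document set must be a subset of the gold document set;
    tags are deduplicated per document before counting.
    """
    if empty_empty not in ("skip", "zero"):
        raise ValueError("empty_empty must be 'skip' or 'zero'")
    gold_docs: dict[str, set[Key]] = {}
    for t in gold:
        gold_docs.setdefault(t.doc_id, set()).add((t.risk_factor, t.indicator, t.time_attr))
    pred_docs: dict[str, set[Key]] = {d: set() for d in gold_docs}
    for t in predicted:
        if t.doc_id not in gold_docs:
            raise CorpusError(f"predicted document {t.doc_id!r} absent from gold")
        pred_docs[t.doc_id].add((t.risk_factor, t.indicator, t.time_attr))

    report = EvalReport(overall=_score(gold_docs, pred_docs, empty_empty))

    def restrict(sel) -> tuple[dict, dict]:
        g = {d: {k for k in ks if sel(k)} for d, ks in gold_docs.items()}
        p = {d: {k for k in ks if sel(k)} for d, ks in pred_docs.items()}
        return g, p

    keys = {k for ks in list(gold_docs.values()) + list(pred_docs.values()) for k in ks}
    for rf in sorted({k[0] for k in keys}):
        report.by_risk_factor[rf] = _score(*restrict(lambda k: k[0] == rf), empty_empty)
    for rf, ind in sorted({(k[0], k[1]) for k in keys}):
        report.by_indicator[(rf, ind)] = _score(
            *restrict(lambda k: k[0] == rf and k[1] == ind), empty_empty
        )
    for rf, t in sorted({(k[0], k[2]) for k in keys if k[2] is not None}):
        report.by_time[(rf, t)] = _score(
            *restrict(lambda k: k[0] == rf and k[2] == t), empty_empty
        )
    return report
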