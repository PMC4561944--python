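"""Multinomial Naive Bayes over string-feature multisets.

Thin deterministic wrapper around scikit-learn's ``MultinomialNB``: the
vocabulary is the sorted set of training features, posteriors tie-break by a
fixed class order supplied at fit time, and models hash stably for
reproducibility checks.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from sklearn.naive_bayes import MultinomialNB


@dataclass
class NaiveBayesModel:
    classes: list[str]  # fixed order; earlier wins posterior ties
    vocabulary: dict[str, int]
    clf: MultinomialNB = field(repr=False)

    def _matrix(self, docs: list[list[str]]) -> csr_matrix:
        rows, cols, vals = [], [], []
        for i, feats in enumerate(docs):
            counts: dict[int, int] = {}
            for f in feats:
                j = self.vocabulary.get(f)
                if j is not None:
                    counts[j] = counts.get(j, 0) + 1
            for j, c in counts.items():
                rows.append(i)
                cols.append(j)
                vals.append(c)
        return csr_matrix(
            (vals, (rows, cols)), shape=(len(docs), len(self.vocabulary))
        )

    def predict(self, feats: list[str]) -> str:
        return self.predict_many([feats])[0]

    def predict_many(self, docs: list[list[str]]) -> list[str]:
        if not docs:
            return []
        logp = self.clf.predict_log_proba(self._matrix(docs))
        # map sklearn's class order onto the fixed tie-break order
        order = [list(self.clf.classes_).index(c) for c in self.classes]
        out = []
        for row in logp:
            vals = row[order]
            out.append(self.classes[int(np.argmax(np.round(vals, 12)))])
        return out

    def model_hash(self) -> str:
        h = hashlib.sha256()
        h.update(repr(self.classes).encode())
        h.update(repr(sorted(self.vocabulary)).encode())
        h.update(np.round(self.clf.feature_log_prob_, 10).tobytes())
        h.update(np.round(self.clf.class_log_prior_, 10).tobytes())
        return h.hexdigest()

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "NaiveBayesModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, NaiveBayesModel):
            raise TypeError(f"{path} does not contain a NaiveBayesModel")
        return model


def train_nb(
    docs: list[list[str]],
    labels: list[str],
    class_order: list[str],
    alpha: float = 1.0,
) -> NaiveBayesModel:
    """Fit additive-smoothed multinomial NB; every class in ``class_order``
    must appear in ``labels``."""
    missing = [c for c in class_order if c not in labels]
    if missing:
        raise ValueError(f"training corpus lacks classes: {missing}")
    unknown = sorted(set(labels) - set(class_order))
    if unknown:
        raise ValueError(f"labels outside the class set: {unknown}")
    vocab = {f: i for i, f in enumerate(sorted({f for d in docs for f in d}))}
    model = NaiveBayesModel(list(class_order), vocab, MultinomialNB(alpha=alpha))
    model.clf.fit(model._matrix(docs), labels)
    return model
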