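"""A small linear-chain conditional random field for sentence-sequence labeling.

Maximum-likelihood training with L2 regularization via L-BFGS; exact
inference with forward-backward (gradients) and Viterbi (decoding).
Observations are sets of string features per position; the feature space is
the cross product of observed feature strings and labels, plus label-bigram
transition weights.  Deliberately minimal: dense weight vector, no feature
hashing — adequate for sentence sequences with a few hundred templates.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


@dataclass
class ChainCRF:
    labels: list[str]
    features: list[str]
    state_weights: np.ndarray  # (n_features, n_labels)
    trans_weights: np.ndarray  # (n_labels, n_labels), trans[i, j] = i -> j
    init_weights: np.ndarray  # (n_labels,)
    feature_index: dict[str, int]

    def _emissions(self, seq: list[set[str]]) -> np.ndarray:
        """Log-potential of each label at each position."""
        em = np.zeros((len(seq), len(self.labels)))
        for t, feats in enumerate(seq):
            for f in feats:
                j = self.feature_index.get(f)
                if j is not None:
                    em[t] += self.state_weights[j]
        return em

    def decode(self, seq: list[set[str]]) -> list[str]:
        """Viterbi-best label sequence; ties break toward the lower label index."""
        if not seq:
            return []
        em = self._emissions(seq)
        n, k = em.shape
        delta = em[0] + self.init_weights
        back = np.zeros((n, k), dtype=int)
        for t in range(1, n):
            scores = delta[:, None] + self.trans_weights + em[t][None, :]
            back[t] = np.argmax(scores, axis=0)
            delta = scores[back[t], np.arange(k)]
        path = [int(np.argmax(delta))]
        for t in range(n - 1, 0, -1):
            path.append(int(back[t][path[-1]]))
        return [self.labels[i] for i in reversed(path)]

    def model_hash(self) -> str:
        """Stable digest of labels, features, and weights."""
        h = hashlib.sha256()
        h.update(repr(self.labels).encode())
        h.update(repr(self.features).encode())
        for arr in (self.state_weights, self.trans_weights, self.init_weights):
            h.update(np.round(arr, 10).tobytes())
        return h.hexdigest()

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "ChainCRF":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, ChainCRF):
            raise TypeError(f"{path} does not contain a ChainCRF model")
        return model


def train_crf(
    sequences: list[list[set[str]]],
    label_seqs: list[list[str]],
    c2: float = 0.1,
    max_iter: int = 150,
) -> ChainCRF:
    """Fit a chain CRF by penalized maximum likelihood.

    ``sequences[i][t]`` is the feature set of position t of sequence i and
    ``label_seqs[i][t]`` its label.  Deterministic for fixed input order:
    features and labels are indexed in sorted order and optimization starts
    from zeros.
    """
    if not sequences or len(sequences) != len(label_seqs):
        raise ValueError("need equally many non-empty feature and label sequences")
    labels = sorted({l for ls in label_seqs for l in ls})
    features = sorted({f for seq in sequences for fs in seq for f in fs})
    lab_index = {l: i for i, l in enumerate(labels)}
    feat_index = {f: i for i, f in enumerate(features)}
    nf, nl = len(features), len(labels)

    data = []
    for seq, labs in zip(sequences, label_seqs):
        if len(seq) != len(labs):
            raise ValueError("feature/label sequence length mismatch")
        rows = [np.fromiter((feat_index[f] for f in fs), dtype=int) for fs in seq]
        data.append((rows, np.array([lab_index[l] for l in labs], dtype=int)))

    def unpack(theta):
        sw = theta[: nf * nl].reshape(nf, nl)
        tw = theta[nf * nl : nf * nl + nl * nl].reshape(nl, nl)
        iw = theta[nf * nl + nl * nl :]
        return sw, tw, iw

    def objective(theta):
        sw, tw, iw = unpack(theta)
        g_sw = np.zeros_like(sw)
        g_tw = np.zeros_like(tw)
        g_iw = np.zeros_like(iw)
        nll = 0.0
        for rows, y in data:
            n = len(rows)
            em = np.zeros((n, nl))
            for t, r in enumerate(rows):
                if r.size:
                    em[t] = sw[r].sum(axis=0)
            # forward/backward in log space
            alpha = np.zeros((n, nl))
            alpha[0] = iw + em[0]
            for t in range(1, n):
                alpha[t] = em[t] + logsumexp(alpha[t - 1][:, None] + tw, axis=0)
            beta = np.zeros((n, nl))
            for t in range(n - 2, -1, -1):
                beta[t] = logsumexp(tw + (em[t + 1] + beta[t + 1])[None, :], axis=1)
            logz = logsumexp(alpha[-1])

            score = iw[y[0]] + em[np.arange(n), y].sum()
            score += tw[y[:-1], y[1:]].sum() if n > 1 else 0.0
            nll += logz - score

            node_marg = np.exp(alpha + beta - logz)  # (n, nl)
            for t, r in enumerate(rows):
                if r.size:
                    np.add.at(g_sw, r, node_marg[t])
                g_sw[r, y[t]] -= 1.0 if r.size else 0.0
            g_iw += node_marg[0]
            g_iw[y[0]] -= 1.0
            for t in range(1, n):
                pair = (
                    alpha[t - 1][:, None] + tw + (em[t] + beta[t])[None, :] - logz
                )
                g_tw += np.exp(pair)
                g_tw[y[t - 1], y[t]] -= 1.0
        nll += c2 * (theta @ theta)
        grad = np.concatenate([g_sw.ravel(), g_tw.ravel(), g_iw]) + 2 * c2 * theta
        return nll, grad

    theta0 = np.zeros(nf * nl + nl * nl + nl)
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter})
    sw, tw, iw = unpack(res.x)
    return ChainCRF(labels, features, sw, tw, iw, feat_index)
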