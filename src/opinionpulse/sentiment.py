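"""Three-class polarity classification with multinomial Naïve Bayes.

The posterior for a post is

    P(polarity | tokens)  ∝  P(polarity) · Π_t P(t | polarity)

with class priors estimated from label frequencies and per-class token
likelihoods estimated with additive (Laplace) smoothing over a
bag-of-words unigram model.  Out-of-vocabulary tokens contribute nothing
at classification time, so a post with no known tokens falls back to the
class priors.

If the input corpus already carries polarity labels the pipeline skips
this classifier entirely; that bypass is the faithful route when the
labels come from an external tool.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import POLARITIES

_TOKEN_SPLIT = re.compile(r"[^0-9a-z]+")

#: floor for a token log-likelihood, so classification stays total even
#: with smoothing 0 (exp(-745) is the smallest positive normal double).
LOG_FLOOR = -745.0


def tokenize(text: str) -> list[str]:
    """Lowercase, split on non-alphanumeric runs, keep tokens of length >= 2."""
    return [t for t in _TOKEN_SPLIT.split(text.lower()) if len(t) >= 2]


class MultinomialPolarityClassifier(BaseEstimator, ClassifierMixin):
    """Multinomial Naïve Bayes over the fixed three polarity classes.

    Parameters
    ----------
    smoothing : float, default 1.0
        Additive pseudo-count per (token, class).  ``0`` is accepted; the
        resulting zero likelihoods are floored in log space.

    Attributes
    ----------
    classes_ : ndarray of shape (3,)
        Always ``(positive, neutral, negative)`` — ties at prediction
        time resolve in this order.
    class_prior_ : ndarray of shape (3,)
    vocabulary_ : dict[str, int]
    feature_log_prob_ : ndarray of shape (3, n_vocab)
    """

    def __init__(self, smoothing: float = 1.0):
        self.smoothing = smoothing

    def fit(self, X: Sequence[str], y: Sequence[str]):
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        X = list(X)
        y = list(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.array(POLARITIES, dtype=object)
        counts = {c: 0 for c in POLARITIES}
        for label in y:
            if label not in counts:
                raise ValueError(f"unknown polarity label {label!r}")
            counts[label] += 1
        empty = [c for c, n in counts.items() if n == 0]
        if empty:
            raise ValueError(
                f"cannot train: no documents for class(es) {empty}"
            )
        vocab: dict[str, int] = {}
        docs_tokens = [tokenize(t) for t in X]
        for toks in docs_tokens:
            for t in toks:
                if t not in vocab:
                    vocab[t] = len(vocab)
        self.vocabulary_ = vocab
        n_vocab = len(vocab)
        token_counts = np.zeros((3, n_vocab))
        for toks, label in zip(docs_tokens, y):
            k = POLARITIES.index(label)
            for t in toks:
                token_counts[k, vocab[t]] += 1
        total = len(y)
        self.class_count_ = np.array([counts[c] for c in POLARITIES], float)
        self.class_prior_ = self.class_count_ / total
        denom = token_counts.sum(axis=1, keepdims=True) + self.smoothing * n_vocab
        with np.errstate(divide="ignore", invalid="ignore"):
            probs = (token_counts + self.smoothing) / denom
            logp = np.log(probs)
        logp = np.where(np.isfinite(logp), logp, LOG_FLOOR)
        # a class with no tokens and no smoothing has an empty
        # distribution; keep the floor there too
        logp = np.nan_to_num(logp, nan=LOG_FLOOR)
        self.feature_log_prob_ = np.maximum(logp, LOG_FLOOR)
        self.feature_count_ = token_counts
        return self

    def _check_fitted(self):
        if not hasattr(self, "feature_log_prob_"):
            raise ValueError("classifier is not fitted")

    def _joint_log_likelihood(self, texts: Iterable[str]) -> np.ndarray:
        self._check_fitted()
        out = []
        log_prior = np.log(self.class_prior_)
        for text in texts:
            ll = log_prior.copy()
            for t in tokenize(text):
                j = self.vocabulary_.get(t)
                if j is not None:
                    ll = ll + self.feature_log_prob_[:, j]
            out.append(ll)
        return np.array(out).reshape(-1, 3)

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        """Posterior polarity probabilities, rows summing to 1."""
        jll = self._joint_log_likelihood(X)
        jll = jll - jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: Sequence[str]) -> np.ndarray:
        proba = self.predict_proba(X)
        # np.argmax returns the first maximum: positive > neutral > negative
        return self.classes_[np.argmax(proba, axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=object)))

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        self._check_fitted()
        return json.dumps({
            "smoothing": self.smoothing,
            "class_prior": self.class_prior_.tolist(),
            "class_count": self.class_count_.tolist(),
            "vocabulary": self.vocabulary_,
            "feature_log_prob": self.feature_log_prob_.tolist(),
        })

    @classmethod
    def from_json(cls, doc: str) -> "MultinomialPolarityClassifier":
        obj = json.loads(doc)
        model = cls(smoothing=obj["smoothing"])
        model.classes_ = np.array(POLARITIES, dtype=object)
        model.class_prior_ = np.array(obj["class_prior"])
        model.class_count_ = np.array(obj["class_count"])
        model.vocabulary_ = {str(k): int(v) for k, v in obj["vocabulary"].items()}
        model.feature_log_prob_ = np.array(obj["feature_log_prob"])
        model.feature_count_ = None
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "MultinomialPolarityClassifier":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


# -- thin functional wrappers ------------------------------------------------

def train_nb(labeled: Iterable[tuple[str, str]],
             smoothing: float = 1.0) -> MultinomialPolarityClassifier:
    """Train a classifier from ``(text, polarity)`` pairs."""
    pairs = list(labeled)
    texts = [t for t, _ in pairs]
    labels = [p for _, p in pairs]
    return MultinomialPolarityClassifier(smoothing=smoothing).fit(texts, labels)


def classify(model: MultinomialPolarityClassifier,
             text: str) -> tuple[str, np.ndarray]:
    """Classify one post; returns ``(polarity, posterior 3-vector)``."""
    proba = model.predict_proba([text])[0]
    label = model.classes_[int(np.argmax(proba))]
    return str(label), proba
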