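"""Keyword-lexicon topic tagging and n-gram diagnostics.

Posts are tagged with up to three vaccine aspects — vaccine type,
phased vaccination, health concern — by whole-token phrase matching
against a lexicon (the shipped default transcribes the published
keyword table).  Token matching rather than raw substring search keeps
"old" from firing inside "golden".  Ranked bigrams/trigrams over a
corpus serve as the lexicon-validation diagnostic.
"""

from __future__ import annotations

from collections import Counter
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .io import TweetRecord
from .sentiment import tokenize

TOPIC_NAMES: tuple[str, ...] = (
    "vaccine_type", "phased_vaccination", "health_concern",
)

#: small built-in stop list, applied to n-gram extraction only
STOPWORDS = frozenset(
    "the a an and or of to in on at for my your our is are was were be been "
    "it its this that with as by from has have had not no so do does did am "
    "we you they he she them his her their me us i if but about just get got "
    "will would can could all out up".split()
)


class TopicLexicon:
    """Mapping of topic name -> list of lowercase token phrases."""

    def __init__(self, phrases: Mapping[str, Sequence[str]]):
        unknown = set(phrases) - set(TOPIC_NAMES)
        if unknown:
            raise ValueError(f"unknown topic names: {sorted(unknown)}")
        missing = set(TOPIC_NAMES) - set(phrases)
        if missing:
            raise ValueError(f"lexicon missing topics: {sorted(missing)}")
        self._phrases: dict[str, list[tuple[str, ...]]] = {}
        for topic in TOPIC_NAMES:
            toks = []
            for phrase in phrases[topic]:
                t = tuple(tokenize(phrase))
                if not t:
                    raise ValueError(f"phrase {phrase!r} tokenizes to nothing")
                toks.append(t)
            # dedupe, preserving order (the published table repeats "fever")
            seen: dict[tuple[str, ...], None] = {}
            for t in toks:
                seen.setdefault(t)
            self._phrases[topic] = list(seen)
        self.topics = TOPIC_NAMES

    def phrases(self, topic: str) -> list[tuple[str, ...]]:
        return list(self._phrases[topic])

    def as_dict(self) -> dict[str, list[str]]:
        return {t: [" ".join(p) for p in self._phrases[t]] for t in TOPIC_NAMES}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TopicLexicon":
        with open(path, encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh))


def default_lexicon() -> TopicLexicon:
    """The shipped three-aspect lexicon."""
    with resources.as_file(
        resources.files("opinionpulse.data") / "topic_lexicon.yaml"
    ) as p:
        return TopicLexicon.from_yaml(p)


def _contains_phrase(tokens: Sequence[str], phrase: tuple[str, ...]) -> bool:
    n = len(phrase)
    return any(tuple(tokens[i:i + n]) == phrase
               for i in range(len(tokens) - n + 1))


def tag_topics(text: str, lexicon: TopicLexicon | None = None) -> set[str]:
    """Topics whose lexicon contains a phrase present in the text.

    Matching is on the tokenized text: a multi-word phrase must appear
    as consecutive tokens.  A post may receive 0–3 topics.
    """
    lexicon = lexicon or default_lexicon()
    tokens = tokenize(text)
    return {
        topic for topic in lexicon.topics
        if any(_contains_phrase(tokens, p) for p in lexicon.phrases(topic))
    }


class TopicTagger(BaseEstimator, TransformerMixin):
    """Transformer adding a ``topics`` column (sorted tuple per post)."""

    def __init__(self, lexicon: TopicLexicon | None = None):
        self.lexicon = lexicon

    def fit(self, X=None, y=None):
        self.lexicon_ = self.lexicon or default_lexicon()
        return self

    def transform(self, X):
        if not hasattr(self, "lexicon_"):
            self.fit()
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            out = X.copy()
            out["topics"] = [
                tuple(sorted(tag_topics(t, self.lexicon_))) for t in out["text"]
            ]
            return out
        return [tuple(sorted(tag_topics(t, self.lexicon_))) for t in X]


def extract_ngrams(corpus: Iterable, n: int, top_k: int,
                   remove_stopwords: bool = True) -> list[tuple[str, int]]:
    """Most frequent within-post n-grams, ties broken lexicographically.

    ``corpus`` may contain raw strings or :class:`TweetRecord`.
    """
    if n not in (2, 3):
        raise ValueError("n must be 2 or 3")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    counts: Counter[tuple[str, ...]] = Counter()
    for item in corpus:
        text = item.tweet_text if isinstance(item, TweetRecord) else str(item)
        tokens = tokenize(text)
        if remove_stopwords:
            tokens = [t for t in tokens if t not in STOPWORDS]
        for i in range(len(tokens) - n + 1):
            counts[tuple(tokens[i:i + n])] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(" ".join(gram), c) for gram, c in ranked[:top_k]]
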