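from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from opinionpulse import (
    MultinomialPolarityClassifier,
    classify,
    generate_labeled_sentiment_corpus,
    tokenize,
    train_nb,
)
from opinionpulse.io import POLARITIES


class TestTokenize:
    @pytest.mark.parametrize("text,expected", [
        ("Got my Pfizer shot!", ["got", "my", "pfizer", "shot"]),
        ("", []),
        ("COVID-19 vaccine", ["covid", "19", "vaccine"]),
        ("a b cd", ["cd"]),  # single-character tokens dropped
    ])
    def test_rules(self, text, expected):
        assert tokenize(text) == expected


# --- exact-enumeration oracle for the NB posterior ------------------------

def nb_oracle(corpus, text, smoothing=1):
    """Posterior over POLARITIES by direct rational evaluation of
    prior * product(token likelihoods), Laplace-smoothed."""
    smoothing = Fraction(smoothing)
    vocab = sorted({t for doc, _ in corpus for t in tokenize(doc)})
    V = len(vocab)
    total = len(corpus)
    post = []
    for pol in POLARITIES:
        docs = [doc for doc, label in corpus if label == pol]
        prior = Fraction(len(docs), total)
        class_tokens = [t for doc in docs for t in tokenize(doc)]
        denom = len(class_tokens) + smoothing * V
        p = prior
        for t in tokenize(text):
            if t in vocab:
                p *= Fraction(class_tokens.count(t) + smoothing, denom)
        post.append(p)
    z = sum(post)
    if z == 0:
        return None
    return [p / z for p in post]


def oracle_label(posterior):
    best = max(posterior)
    return POLARITIES[posterior.index(best)]  # first max: fixed tie order


THREE_DOC_CORPUS = [("good good", "positive"), ("bad", "negative"),
                    ("ok", "neutral")]


class TestTraining:
    def test_class_priors_from_label_frequencies(self):
        corpus = [("a b", "positive"), ("c d", "positive"),
                  ("e f", "negative"), ("g h", "neutral")]
        model = train_nb(corpus)
        np.testing.assert_allclose(model.class_prior_, [0.5, 0.25, 0.25])

    def test_laplace_token_likelihood_hand_computed(self):
        # P(good|pos) = (2+1)/(2+3) with |V| = 3
        model = train_nb(THREE_DOC_CORPUS, smoothing=1)
        j = model.vocabulary_["good"]
        assert np.exp(model.feature_log_prob_[0, j]) == pytest.approx(0.6)

    def test_token_distributions_sum_to_one_per_class(self):
        model = train_nb(THREE_DOC_CORPUS)
        np.testing.assert_allclose(
            np.exp(model.feature_log_prob_).sum(axis=1), np.ones(3))

    def test_missing_class_is_fatal_and_named(self):
        with pytest.raises(ValueError, match="neutral"):
            train_nb([("a", "positive"), ("b", "negative")])

    def test_zero_smoothing_keeps_classify_total(self):
        model = train_nb(THREE_DOC_CORPUS, smoothing=0)
        label, post = classify(model, "good bad ok")
        assert np.isfinite(post).all()
        assert post.sum() == pytest.approx(1.0)


class TestClassify:
    def test_unknown_tokens_fall_back_to_priors(self):
        model = train_nb(THREE_DOC_CORPUS)
        _, post = classify(model, "zzz qqq")
        np.testing.assert_allclose(post, model.class_prior_)

    def test_hand_example_good_is_positive(self):
        model = train_nb(THREE_DOC_CORPUS)
        label, post = classify(model, "good")
        assert label == "positive"
        expected = nb_oracle(THREE_DOC_CORPUS, "good")
        np.testing.assert_allclose(post, [float(p) for p in expected],
                                   rtol=1e-12)

    def test_separable_corpus_training_accuracy_one(self):
        docs = generate_labeled_sentiment_corpus(30, 1.0, seed=4)
        model = train_nb(docs)
        assert model.score([t for t, _ in docs], [p for _, p in docs]) == 1.0

    def test_label_permutation_equivariance(self):
        # swapping the positive and negative training labels swaps the
        # corresponding posterior entries
        corpus = [("aa bb", "positive"), ("aa", "positive"),
                  ("cc dd", "negative"), ("ee", "neutral")]
        swap = {"positive": "negative", "negative": "positive",
                "neutral": "neutral"}
        swapped = [(t, swap[p]) for t, p in corpus]
        m1 = train_nb(corpus)
        m2 = train_nb(swapped)
        for text in ("aa bb", "cc", "ee aa", "zz"):
            p1 = m1.predict_proba([text])[0]
            p2 = m2.predict_proba([text])[0]
            np.testing.assert_allclose(p1, p2[[2, 1, 0]], rtol=1e-12)


words = st.sampled_from(["aa", "bb", "cc", "dd", "ee", "ff", "gg", "hh"])
docs = st.lists(words, min_size=1, max_size=5).map(" ".join)


@st.composite
def corpora(draw):
    """Up to 10 documents over an 8-token vocabulary, every class present."""
    labels = list(POLARITIES)
    n_extra = draw(st.integers(min_value=0, max_value=7))
    corpus = [(draw(docs), lab) for lab in labels]
    corpus += [(draw(docs), draw(st.sampled_from(labels)))
               for _ in range(n_extra)]
    return corpus


class TestOracleEquivalence:
    @given(corpus=corpora(), text=docs)
    def test_posterior_matches_exact_enumeration(self, corpus, text):
        model = train_nb(corpus, smoothing=1)
        label, post = classify(model, text)
        exact = nb_oracle(corpus, text, smoothing=1)
        np.testing.assert_allclose(post, [float(p) for p in exact],
                                   rtol=1e-9, atol=1e-12)
        ranked = sorted(exact, reverse=True)
        gap = float(ranked[0] - ranked[1])
        if gap > 1e-9:
            assert label == oracle_label(exact)
        else:  # exact tie: any maximal label in fixed priority order
            tied = {POLARITIES[i] for i, p in enumerate(exact)
                    if ranked[0] - p <= Fraction(1, 10**9)}
            assert label in tied

    @given(corpus=corpora(), text=docs)
    def test_posterior_is_probability_vector(self, corpus, text):
        model = train_nb(corpus)
        _, post = classify(model, text)
        assert post.sum() == pytest.approx(1.0, abs=1e-12)
        assert (post >= 0).all()


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self):
        docs = generate_labeled_sentiment_corpus(10, 0.7, seed=8)
        model = train_nb(docs)
        clone = MultinomialPolarityClassifier.from_json(model.to_json())
        texts = [t for t, _ in docs]
        np.testing.assert_array_equal(model.predict(texts), clone.predict(texts))
        np.testing.assert_allclose(model.predict_proba(texts),
                                   clone.predict_proba(texts))
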