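"""Latent Dirichlet allocation by collapsed Gibbs sampling, plus topic
screening for depression-indicative content.

The sampler integrates out the topic–word and document–topic distributions
and resamples each token's topic assignment from the collapsed conditional

    p(z_i = k | z_-i, w) ∝ (n_dk + α) (n_kw + β) / (n_k + V β)

where the counts exclude token *i*.  After ``n_iter`` full sweeps the
point estimates are read off the final count tables with Dirichlet
smoothing:

    φ_kw = (n_kw + β) / (n_k + V β),   θ_dk = (n_dk + α) / (n_d + K α).

Symmetric priors with α = β = 0.01 are the package defaults.  Topics are
summarised by their top-15 highest-probability words and screened for
depression-indicative content against a lexicon bundle — a reproducible
rule standing in for expert validation of topics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import FeatureMatrix, LexiconBundle
from .preprocess import Tweet

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
DEFAULT_BETA = 0.01
DEFAULT_TOPICS = 50
DEFAULT_TOP_WORDS = 15
NEGATIVE_CATEGORIES = ("psych:negemo", "psych:sadness")


@dataclass
class TopicModel:
    """Fitted K-topic model with its final assignment state."""

    K: int
    alpha: float
    beta: float
    phi: np.ndarray               # K x V
    theta: np.ndarray             # D x K
    vocab: list[str]
    doc_ids: list[str]
    assignments: list[np.ndarray]  # per-document token topic assignments
    doc_words: list[np.ndarray]    # per-document token word indices
    seed: int = 0
    n_iter: int = 0
    loglik_trace: np.ndarray | None = None

    @property
    def V(self) -> int:
        return len(self.vocab)

    def word_index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.vocab)}


@dataclass
class TopicScreenResult:
    """Outcome of screening one topic for depression-indicative words."""

    topic_id: int
    top_words: list[tuple[str, float]]
    matched_depression_words: frozenset
    indicative: bool


def save_model(model: TopicModel, path) -> None:
    """Serialize a fitted model to a single JSON document (φ, θ and the
    assignment state as nested lists; suitable for desk-scale models)."""
    import json

    doc = {
        "K": model.K, "alpha": model.alpha, "beta": model.beta,
        "vocab": model.vocab, "doc_ids": model.doc_ids,
        "phi": model.phi.tolist(), "theta": model.theta.tolist(),
        "assignments": [z.tolist() for z in model.assignments],
        "doc_words": [w.tolist() for w in model.doc_words],
        "seed": model.seed, "n_iter": model.n_iter,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> TopicModel:
    import json

    with open(path) as fh:
        doc = json.load(fh)
    return TopicModel(
        K=doc["K"], alpha=doc["alpha"], beta=doc["beta"],
        phi=np.array(doc["phi"]), theta=np.array(doc["theta"]),
        vocab=doc["vocab"], doc_ids=doc["doc_ids"],
        assignments=[np.array(z, dtype=np.intp) for z in doc["assignments"]],
        doc_words=[np.array(w, dtype=np.intp) for w in doc["doc_words"]],
        seed=doc["seed"], n_iter=doc["n_iter"],
    )


def _docs_of(corpus) -> tuple[list[str], list[list[str]]]:
    if corpus and isinstance(corpus[0], Tweet):
        return [t.id for t in corpus], [t.tokens for t in corpus]
    return [str(i) for i in range(len(corpus))], [list(d) for d in corpus]


def token_conditional(n_dk_row: np.ndarray, n_kw_col: np.ndarray, n_k: np.ndarray,
                      alpha: float, beta: float, V: int) -> np.ndarray:
    """Normalized collapsed conditional p(z_i = k | z_-i, w_i) given count
    tables that already exclude token *i*."""
    p = (n_dk_row + alpha) * (n_kw_col + beta) / (n_k + V * beta)
    return p / p.sum()


def _corpus_log_likelihood(n_dk, n_kw, n_k, n_d, alpha, beta, doc_words, assignments):
    """log p(w | current point estimates of φ, θ)."""
    K, V = n_kw.shape
    phi = (n_kw + beta) / (n_k + V * beta)[:, None]
    theta = (n_dk + alpha) / (n_d + K * alpha)[:, None]
    ll = 0.0
    for d, words in enumerate(doc_words):
        if len(words):
            ll += float(np.log(theta[d] @ phi[:, words]).sum())
    return ll


def fit_lda(corpus, K: int, alpha: float = DEFAULT_ALPHA, beta: float = DEFAULT_BETA,
            n_iter: int = 500, seed: int = 0,
            track_likelihood: bool = False,
            check_counts: bool = False) -> TopicModel:
    """Fit a K-topic model by collapsed Gibbs sampling.

    ``corpus`` is a sequence of tokenized tweets or plain token lists; all
    documents must be non-empty.  The run is deterministic given ``seed``.
    With ``check_counts`` the count tables are verified for conservation
    after every sweep (total topic counts equal the corpus token count).
    """
    doc_ids, docs = _docs_of(corpus)
    if not docs:
        raise ValueError("empty corpus")
    if K < 2:
        raise ValueError("K must be >= 2")
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    vocab = sorted({w for d in docs for w in d})
    if not vocab:
        raise ValueError("vocabulary size 0: all documents are empty")
    for d_id, d in zip(doc_ids, docs):
        if not d:
            raise ValueError(f"document {d_id} is empty")
    if K > len(docs):
        warnings.warn(f"K={K} exceeds the number of documents ({len(docs)})")
    widx = {w: i for i, w in enumerate(vocab)}
    V, D = len(vocab), len(docs)

    rng = np.random.default_rng(seed)
    doc_words = [np.array([widx[w] for w in d], dtype=np.intp) for d in docs]
    n_d = np.array([len(d) for d in docs], dtype=float)

    n_dk = np.zeros((D, K))
    n_kw = np.zeros((K, V))
    n_k = np.zeros(K)
    z: list[np.ndarray] = []
    for d, words in enumerate(doc_words):
        zd = rng.integers(0, K, size=len(words))
        z.append(zd)
        for w, k in zip(words, zd):
            n_dk[d, k] += 1
            n_kw[k, w] += 1
            n_k[k] += 1

    trace = []
    Vbeta = V * beta
    for sweep in range(n_iter):
        u = rng.random(int(n_d.sum()))
        ui = 0
        for d, words in enumerate(doc_words):
            zd = z[d]
            row = n_dk[d]
            for i in range(len(words)):
                w = words[i]
                k = zd[i]
                row[k] -= 1
                n_kw[k, w] -= 1
                n_k[k] -= 1
                p = (row + alpha) * (n_kw[:, w] + beta) / (n_k + Vbeta)
                cp = np.cumsum(p)
                k = int(np.searchsorted(cp, u[ui] * cp[-1], side="right"))
                ui += 1
                zd[i] = k
                row[k] += 1
                n_kw[k, w] += 1
                n_k[k] += 1
        if check_counts:
            total = int(n_d.sum())
            if not (int(n_k.sum()) == total
                    and np.array_equal(n_dk.sum(axis=1), n_d)
                    and np.array_equal(n_kw.sum(axis=1), n_k)):
                raise AssertionError(f"count tables inconsistent after sweep {sweep}")
        if track_likelihood:
            trace.append(_corpus_log_likelihood(n_dk, n_kw, n_k, n_d, alpha, beta,
                                                doc_words, z))

    phi = (n_kw + beta) / (n_k + Vbeta)[:, None]
    theta = (n_dk + alpha) / (n_d + K * alpha)[:, None]
    return TopicModel(
        K=K, alpha=alpha, beta=beta, phi=phi, theta=theta, vocab=vocab,
        doc_ids=doc_ids, assignments=z, doc_words=doc_words,
        seed=seed, n_iter=n_iter,
        loglik_trace=np.array(trace) if track_likelihood else None,
    )


def fold_in(model: TopicModel, docs: Sequence[Sequence[str]],
            n_iter: int = 50, seed: int = 0) -> np.ndarray:
    """Estimate document–topic mixtures for unseen documents by Gibbs
    sweeps with φ held fixed; out-of-vocabulary tokens are ignored, so an
    all-OOV document falls back to the uniform prior mixture 1/K."""
    rng = np.random.default_rng(seed)
    widx = model.word_index()
    K = model.K
    out = np.zeros((len(docs), K))
    for d, doc in enumerate(docs):
        words = np.array([widx[w] for w in doc if w in widx], dtype=np.intp)
        n = len(words)
        if n == 0:
            out[d] = 1.0 / K
            continue
        zd = rng.integers(0, K, size=n)
        counts = np.bincount(zd, minlength=K).astype(float)
        for _ in range(n_iter):
            for i in range(n):
                k = zd[i]
                counts[k] -= 1
                p = (counts + model.alpha) * model.phi[:, words[i]]
                k = int(rng.choice(K, p=p / p.sum()))
                zd[i] = k
                counts[k] += 1
        out[d] = (counts + model.alpha) / (n + K * model.alpha)
    return out


def topic_features(model: TopicModel, corpus=None,
                   n_iter: int = 50, seed: int = 0) -> FeatureMatrix:
    """One column per topic.  Documents seen at fit time get their fitted
    θ rows; new documents are folded in with fixed φ."""
    names = [f"lda:{k}" for k in range(model.K)]
    if corpus is None:
        ids, X = model.doc_ids, model.theta
    else:
        ids, docs = _docs_of(corpus)
        fitted = {d: i for i, d in enumerate(model.doc_ids)}
        if all(d in fitted for d in ids):
            X = model.theta[[fitted[d] for d in ids]]
        else:
            X = fold_in(model, docs, n_iter=n_iter, seed=seed)
    return FeatureMatrix(list(ids), names, np.asarray(X, dtype=float),
                         {"lda": slice(0, model.K)})


def top_words(model: TopicModel, topic_id: int,
              n: int = DEFAULT_TOP_WORDS) -> list[tuple[str, float]]:
    """The ``n`` highest-probability words of a topic, ties broken
    lexicographically."""
    if not (0 <= topic_id < model.K):
        raise IndexError(f"topic_id {topic_id} out of range [0, {model.K})")
    row = model.phi[topic_id]
    order = sorted(range(model.V), key=lambda i: (-row[i], model.vocab[i]))
    return [(model.vocab[i], float(row[i])) for i in order[: min(n, model.V)]]


def screen_topic(model: TopicModel, topic_id: int, bundle: LexiconBundle,
                 m: int = 2, n_top: int = DEFAULT_TOP_WORDS) -> TopicScreenResult:
    """Mark a topic depression-indicative if at least ``m`` of its top
    words are non-joy glossary words, or at least ``m`` fall in a
    negative-emotion/sadness category."""
    tw = top_words(model, topic_id, n_top)
    words = [w for w, _ in tw]
    gloss = bundle.glossary_nonjoy()
    gloss_hits = {w for w in words if w in gloss}
    neg_hits = set()
    for cat in NEGATIVE_CATEGORIES:
        entry = bundle.category_dict.get(cat)
        if entry is not None:
            neg_hits |= {w for w in words if entry.matches(w)}
    indicative = len(gloss_hits) >= m or len(neg_hits) >= m
    return TopicScreenResult(
        topic_id=topic_id,
        top_words=tw,
        matched_depression_words=frozenset(gloss_hits | neg_hits),
        indicative=indicative,
    )


def screen_all(model: TopicModel, bundle: LexiconBundle,
               m: int = 2, n_top: int = DEFAULT_TOP_WORDS) -> list[TopicScreenResult]:
    return [screen_topic(model, k, bundle, m, n_top) for k in range(model.K)]


def experimental_group(corpus: Sequence[Tweet], model: TopicModel,
                       screen: Sequence[TopicScreenResult],
                       engage_threshold: float = 0.2,
                       min_tweets: int = 5,
                       theta: np.ndarray | None = None) -> set[str]:
    """Users engaging with at least one depression-indicative topic (some
    tweet's topic weight ≥ ``engage_threshold``) who have at least
    ``min_tweets`` tweets."""
    indicative = [s.topic_id for s in screen if s.indicative]
    if not indicative:
        return set()
    if theta is None:
        theta = topic_features(model, corpus).values
    counts: dict[str, int] = {}
    engaged: set[str] = set()
    for i, t in enumerate(corpus):
        counts[t.user_id] = counts.get(t.user_id, 0) + 1
        if (theta[i, indicative] >= engage_threshold).any():
            engaged.add(t.user_id)
    return {u for u in engaged if counts[u] >= min_tweets}
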