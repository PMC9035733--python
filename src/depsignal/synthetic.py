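"""Synthetic corpora with planted topic and depression-vocabulary structure.

Real keyword-collected tweet corpora of the kind this package analyses are
not redistributable, so every downstream stage is exercised on generated
data whose ground truth is known.  The generator emulates the statistical
shape the analysis assumes:

* users each posting at least five timestamped tweets spread over weeks;
* documents drawn from a Dirichlet–multinomial topic process with
  ``K_true`` planted topics;
* a controllable fraction of the vocabulary designated depression-related,
  assigned to topics under two regimes: *low* cross-topic overlap (each
  topic carries a near-disjoint slice of the depression vocabulary, the
  "before" condition) and *high* overlap (topics share most of it, the
  "during" condition);
* a per-user continuous depression-signal score that is a planted linear
  function of the user's expected topic mixture plus Gaussian noise, with
  binary labels by median split.

Words are synthetic tokens ("w0001", …): set and count semantics are
preserved without shipping any clinical vocabulary.  Every tweet text is
prefixed with a planted collection hashtag so the keyword filter retains
it, mirroring how a keyword-collected corpus is born already filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Sequence

import numpy as np

from .features import Category, LexiconBundle
from .preprocess import Tweet

PLANTED_HASHTAG = "#StayHome"
NORM_PROPERTIES = ("familiarity", "concreteness", "imagery")
JOY_FRACTION = 0.1  # fraction of glossary words tagged "joy", exercising the discard rule


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults are the package's study conditions
    at desk scale."""

    n_users: int = 50
    tweets_per_user: int = 6
    n_weeks: int = 8
    vocab_size: int = 400
    K_true: int = 4
    depression_vocab_fraction: float = 0.15
    overlap_regime: str = "low"
    overlap_level: float | None = None  # default from regime: low=0.1, high=0.8
    alpha_true: float = 0.08
    beta_true: float = 0.01
    signal_coefficients: Sequence[float] | None = None
    noise_sd: float = 0.05
    doc_length_mean: float = 10.0
    period_start: datetime = field(
        default_factory=lambda: datetime(2020, 3, 12, tzinfo=timezone.utc)
    )
    seed: int = 0

    def __post_init__(self):
        if self.overlap_level is None:
            self.overlap_level = {"low": 0.1, "high": 0.8}.get(self.overlap_regime)
        validate_spec(self)

    def resolved_coefficients(self) -> np.ndarray:
        if self.signal_coefficients is not None:
            c = np.asarray(self.signal_coefficients, dtype=float)
            if c.shape != (self.K_true,):
                raise ValueError("signal_coefficients: length must equal K_true")
            return c
        return np.linspace(1.0, -1.0, self.K_true)


def validate_spec(spec: SyntheticSpec) -> None:
    checks = [
        ("n_users", spec.n_users >= 1),
        ("tweets_per_user", spec.tweets_per_user >= 5),
        ("n_weeks", spec.n_weeks >= 1),
        ("K_true", spec.K_true >= 2),
        ("vocab_size", spec.vocab_size >= 10 * spec.K_true),
        ("depression_vocab_fraction", 0.0 <= spec.depression_vocab_fraction <= 1.0),
        ("overlap_regime", spec.overlap_regime in ("low", "high")),
        ("overlap_level", spec.overlap_level is not None and 0.0 <= spec.overlap_level <= 1.0),
        ("alpha_true", spec.alpha_true > 0),
        ("beta_true", spec.beta_true > 0),
        ("noise_sd", spec.noise_sd >= 0),
        ("doc_length_mean", spec.doc_length_mean > 0),
    ]
    for name, ok in checks:
        if not ok:
            raise ValueError(f"invalid SyntheticSpec field: {name}")


@dataclass
class GroundTruth:
    """Planted quantities the tests and recovery experiments check against."""

    doc_ids: list[str]
    vocab: list[str]
    doc_topic_true: np.ndarray        # D x K_true
    topic_word_true: np.ndarray       # K_true x V
    topic_depression_words: list[frozenset]
    depression_vocab: frozenset
    user_ids: list[str]
    user_signal_true: dict[str, float]
    user_label_true: dict[str, int]
    signal_threshold: float


# ---------------------------------------------------------------------------
# Vocabulary plan shared by corpus and lexicons (deterministic in spec alone)

def _vocab(spec: SyntheticSpec) -> list[str]:
    width = max(4, len(str(spec.vocab_size)))
    return [f"w{i:0{width}d}" for i in range(spec.vocab_size)]


def _glossary_words(spec: SyntheticSpec) -> list[str]:
    g = int(round(spec.depression_vocab_fraction * spec.vocab_size))
    return _vocab(spec)[:g]


def _topic_depression_sets(spec: SyntheticSpec) -> tuple[list[str], list[list[str]]]:
    """Split the depression vocabulary into a shared core (overlap_level
    fraction) plus near-disjoint per-topic slices of the remainder."""
    glossary = _glossary_words(spec)
    n_shared = int(round(spec.overlap_level * len(glossary)))
    shared = glossary[:n_shared]
    rest = glossary[n_shared:]
    per_topic: list[list[str]] = []
    K = spec.K_true
    for k in range(K):
        own = rest[k::K]
        per_topic.append(shared + own)
    return glossary, per_topic


# ---------------------------------------------------------------------------
# Lexicons

def generate_lexicons(spec: SyntheticSpec) -> LexiconBundle:
    """Stand-ins for the category dictionary, psychiatric glossary,
    word–emotion lexicon, norm table and synonym map, consistent with the
    corpus ground truth: the glossary *is* the planted depression
    vocabulary."""
    validate_spec(spec)
    rng = np.random.default_rng([spec.seed, 11])
    vocab = _vocab(spec)
    glossary = _glossary_words(spec)

    # every 1/JOY_FRACTION-th glossary word is tagged joy
    joy_step = int(round(1 / JOY_FRACTION))
    emotion_map: dict[str, frozenset] = {}
    for i, w in enumerate(glossary):
        if joy_step and i % joy_step == joy_step - 1:
            emotion_map[w] = frozenset({"joy", "positive"})
        else:
            emotion_map[w] = frozenset({"sadness", "negative"})

    norms = {
        w: {p: float(np.round(rng.uniform(100, 700), 3)) for p in NORM_PROPERTIES}
        for w in glossary
    }

    nonjoy = [w for w in glossary if "joy" not in emotion_map[w]]
    category_dict = {
        "lingdim:firstperson": Category(frozenset({"i", "me", "my", "mine", "myself"})),
        "psych:negemo": Category(frozenset(nonjoy[: max(1, len(nonjoy) // 2)] or ["__none__"])),
        "psych:sadness": Category(frozenset(nonjoy[max(1, len(nonjoy) // 2):] or ["__none__"])),
        "personal:health": Category(
            frozenset(vocab[len(glossary): len(glossary) + max(1, spec.vocab_size // 20)])
        ),
    }

    synonyms = {f"syn_{w}": w for w in glossary[::joy_step or 1][:5]}
    return LexiconBundle(
        category_dict=category_dict,
        glossary=frozenset(glossary),
        emotion_map=emotion_map,
        norms=norms,
        synonyms=synonyms,
    )


# ---------------------------------------------------------------------------
# Corpus

def generate_corpus(spec: SyntheticSpec) -> tuple[list[Tweet], GroundTruth]:
    """Draw a corpus from the planted Dirichlet–multinomial process.

    Topic–word distributions concentrate on a per-topic word block plus the
    topic's depression words (boosted so they surface among top words);
    document mixtures are Dirichlet(``alpha_true``); document lengths are
    5 + Poisson(``doc_length_mean`` − 5), so no zero-length document is
    ever emitted.
    """
    validate_spec(spec)
    rng = np.random.default_rng([spec.seed, 23])
    vocab = _vocab(spec)
    V, K = spec.vocab_size, spec.K_true
    widx = {w: i for i, w in enumerate(vocab)}
    glossary, dep_sets = _topic_depression_sets(spec)
    n_gloss = len(glossary)

    # per-topic blocks of the non-depression vocabulary
    general = vocab[n_gloss:]
    conc = np.full((K, V), spec.beta_true)
    for k in range(K):
        block = general[k::K]
        conc[k, [widx[w] for w in block]] = 0.5
        if dep_sets[k]:
            conc[k, [widx[w] for w in dep_sets[k]]] = 1.0
    topic_word = np.vstack([rng.dirichlet(conc[k]) for k in range(K)])

    user_ids = [f"u{i:04d}" for i in range(spec.n_users)]
    doc_ids: list[str] = []
    tweets: list[Tweet] = []
    thetas = np.zeros((spec.n_users * spec.tweets_per_user, K))
    user_theta_sum: dict[str, np.ndarray] = {u: np.zeros(K) for u in user_ids}
    d = 0
    for u in user_ids:
        for j in range(spec.tweets_per_user):
            theta = rng.dirichlet(np.full(K, spec.alpha_true))
            length = 5 + rng.poisson(max(spec.doc_length_mean - 5, 0.0))
            z = rng.choice(K, size=length, p=theta)
            words = [vocab[rng.choice(V, p=topic_word[k])] for k in z]
            week = j % spec.n_weeks
            ts = (
                spec.period_start
                + timedelta(days=7 * week)
                + timedelta(seconds=float(rng.uniform(0, 7 * 24 * 3600)))
            )
            doc_id = f"t{d:06d}"
            doc_ids.append(doc_id)
            thetas[d] = theta
            user_theta_sum[u] += theta
            tweets.append(
                Tweet(
                    id=doc_id,
                    user_id=u,
                    created_at=ts,
                    text=PLANTED_HASHTAG + " " + " ".join(words),
                    lang="en",
                )
            )
            d += 1

    coeffs = spec.resolved_coefficients()
    signal = {
        u: float(user_theta_sum[u] / spec.tweets_per_user @ coeffs
                 + rng.normal(0, spec.noise_sd))
        for u in user_ids
    }
    threshold = float(np.median(list(signal.values())))
    labels = {u: int(signal[u] >= threshold) for u in user_ids}

    truth = GroundTruth(
        doc_ids=doc_ids,
        vocab=vocab,
        doc_topic_true=thetas,
        topic_word_true=topic_word,
        topic_depression_words=[frozenset(s) for s in dep_sets],
        depression_vocab=frozenset(glossary),
        user_ids=user_ids,
        user_signal_true=signal,
        user_label_true=labels,
        signal_threshold=threshold,
    )
    return tweets, truth
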