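"""Topic-overlap similarity: distribution divergences, word-set overlap,
and the correlation between the two metric families.

Each screened topic is reduced to its top-ten depression-related words
(drawn from the top fifteen by probability, joy-tagged words excluded);
synonym variants are harmonized to canonical forms.  Pairs of topics
within a period are compared by

* Kullback–Leibler divergence ``KL(P‖Q) = Σ p_i ln(p_i/q_i)`` on the union
  support with additive-epsilon smoothing (KL is infinite on disjoint
  supports otherwise);
* the symmetrized smoothed divergence against the mixture M = (P+Q)/2,
  ``½ KL(P‖M) + ½ KL(Q‖M)``, bounded by ln 2 (the Jensen–Shannon form);
* Jaccard similarity |A∩B| / |A∪B| of the harmonized word sets.

Per-period means and the Spearman rank correlation between the set-based
and distribution-based metric (with a permutation p-value) summarise how
strongly depression vocabulary recurs across topics in that period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sstats

from .features import LexiconBundle
from .lda import TopicScreenResult

log = logging.getLogger(__name__)

DEFAULT_RETAIN = 10
DEFAULT_EPSILON = 1e-6
DEFAULT_PERMUTATIONS = 10_000


# ---------------------------------------------------------------------------
# Word retention and harmonization

def depression_word_retention(top_words: Sequence[tuple[str, float]],
                              bundle: LexiconBundle,
                              k: int = DEFAULT_RETAIN) -> list[tuple[str, float]]:
    """The highest-probability ≤ k depression-related words of a topic:
    glossary members not tagged joy, in probability order."""
    gloss = bundle.glossary_nonjoy()
    return [(w, p) for w, p in top_words if w in gloss][:k]


def harmonize(words_a: Sequence[str], words_b: Sequence[str],
              synonyms: Mapping[str, str]) -> tuple[frozenset, frozenset]:
    """Replace every word by its canonical form on both sides (idempotent;
    chains are followed to their terminal canonical form)."""

    def canon(w: str) -> str:
        seen = {w}
        while w in synonyms:
            w = synonyms[w]
            if w in seen:
                raise ValueError(f"cyclic synonym map at {w!r}")
            seen.add(w)
        return w

    return frozenset(canon(w) for w in words_a), frozenset(canon(w) for w in words_b)


# ---------------------------------------------------------------------------
# Divergences

def kl_divergence(p: np.ndarray, q: np.ndarray, epsilon: float = 0.0) -> float:
    """KL(P‖Q) = Σ p_i ln(p_i/q_i) on a shared ordered support; terms with
    p_i = 0 contribute 0.  ``epsilon`` > 0 adds uniform mass to both
    distributions (then renormalizes), which keeps the divergence finite
    on partially disjoint supports."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if epsilon > 0:
        p = (p + epsilon) / (p + epsilon).sum()
        q = (q + epsilon) / (q + epsilon).sum()
    if np.any((q == 0) & (p > 0)):
        raise ValueError("KL undefined: q has zero mass where p > 0 and epsilon <= 0")
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Symmetrized smoothed divergence ½KL(P‖M) + ½KL(Q‖M) with
    M = (P+Q)/2; always defined, symmetric, in [0, ln 2]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)
    return 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)


def jaccard(words_a: frozenset, words_b: frozenset) -> float:
    """|A∩B| / |A∪B|; 0 when both sets are empty."""
    union = set(words_a) | set(words_b)
    if not union:
        return 0.0
    return len(set(words_a) & set(words_b)) / len(union)


# ---------------------------------------------------------------------------
# Per-period pairwise tables

@dataclass
class TopicPairSimilarity:
    period_id: str
    topic_a: int
    topic_b: int
    kl_ab: float
    kl_ba: float
    kl_sym: float            # (kl_ab + kl_ba) / 2, used for averaging
    js_div: float
    jaccard: float
    harmonized: bool = True


@dataclass
class PeriodSummary:
    period_id: str
    n_topics: int
    n_pairs: int
    mean_kl: float
    mean_js: float
    mean_jaccard: float


def _canonical_distribution(retained: Sequence[tuple[str, float]],
                            synonyms: Mapping[str, str]) -> dict[str, float]:
    """Map retained (word, prob) entries to canonical forms, summing the
    probability of variants that collapse to the same word."""
    out: dict[str, float] = {}
    for w, p in retained:
        (cw,) = harmonize([w], [], synonyms)[0]
        out[cw] = out.get(cw, 0.0) + p
    return out


def pair_similarity(dist_a: Mapping[str, float], dist_b: Mapping[str, float],
                    epsilon: float = DEFAULT_EPSILON) -> tuple[float, float, float, float]:
    """KL both directions, the symmetric mixture divergence, and Jaccard
    for two canonical word→probability maps.  Probabilities are
    renormalized over the union support before smoothing."""
    support = sorted(set(dist_a) | set(dist_b))
    p = np.array([dist_a.get(w, 0.0) for w in support])
    q = np.array([dist_b.get(w, 0.0) for w in support])
    if p.sum() > 0:
        p = p / p.sum()
    if q.sum() > 0:
        q = q / q.sum()
    kl_ab = kl_divergence(p, q, epsilon)
    kl_ba = kl_divergence(q, p, epsilon)
    js = js_divergence(p, q)
    jac = jaccard(frozenset(dist_a), frozenset(dist_b))
    return kl_ab, kl_ba, js, jac


def period_similarity(screened: Sequence[TopicScreenResult],
                      bundle: LexiconBundle,
                      period_id: str = "",
                      retain: int = DEFAULT_RETAIN,
                      epsilon: float = DEFAULT_EPSILON,
                      indicative_only: bool = True,
                      ) -> tuple[list[TopicPairSimilarity], PeriodSummary]:
    """All unordered pairs of retained topics in one period.

    Topics without any retained depression word carry no comparable
    vocabulary and are excluded from pairing.
    """
    topics = [s for s in screened if s.indicative or not indicative_only]
    dists: dict[int, dict[str, float]] = {}
    for s in topics:
        retained = depression_word_retention(s.top_words, bundle, retain)
        if retained:
            dists[s.topic_id] = _canonical_distribution(retained, bundle.synonyms)
    ids = sorted(dists)
    pairs: list[TopicPairSimilarity] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            kl_ab, kl_ba, js, jac = pair_similarity(dists[a], dists[b], epsilon)
            pairs.append(TopicPairSimilarity(
                period_id=period_id, topic_a=a, topic_b=b,
                kl_ab=kl_ab, kl_ba=kl_ba, kl_sym=0.5 * (kl_ab + kl_ba),
                js_div=js, jaccard=jac,
            ))
    if len(ids) < 2:
        log.warning("period %s: fewer than 2 retained topics; empty similarity table",
                    period_id or "<unnamed>")
        summary = PeriodSummary(period_id, len(ids), 0,
                                float("nan"), float("nan"), float("nan"))
        return pairs, summary
    summary = PeriodSummary(
        period_id=period_id,
        n_topics=len(ids),
        n_pairs=len(pairs),
        mean_kl=float(np.mean([p.kl_sym for p in pairs])),
        mean_js=float(np.mean([p.js_div for p in pairs])),
        mean_jaccard=float(np.mean([p.jaccard for p in pairs])),
    )
    return pairs, summary


# ---------------------------------------------------------------------------
# Cross-metric correlation

@dataclass
class SpearmanResult:
    rho: float | None
    p_value: float | None
    n_pairs: int
    constant_input: bool = False


def cross_metric_spearman(pairs: Sequence[TopicPairSimilarity],
                          distribution_metric: str = "js",
                          n_permutations: int = DEFAULT_PERMUTATIONS,
                          seed: int = 0) -> SpearmanResult:
    """Spearman ρ between set-based similarity (Jaccard) and negated
    divergence across a period's topic pairs, so that "more similar"
    aligns on both axes; p-value by label permutation."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 topic pairs for a rank correlation")
    set_based = np.array([p.jaccard for p in pairs])
    div = np.array([p.js_div if distribution_metric == "js" else p.kl_sym
                    for p in pairs])
    dist_based = -div
    if np.all(set_based == set_based[0]) or np.all(dist_based == dist_based[0]):
        return SpearmanResult(None, None, len(pairs), constant_input=True)
    rho = float(sstats.spearmanr(set_based, dist_based).statistic)
    rng = np.random.default_rng(seed)
    # Spearman rho is the Pearson correlation of ranks; permuting one rank
    # vector realizes the pair-label-shuffling null
    rx = sstats.rankdata(set_based)
    ry = sstats.rankdata(dist_based)
    rx_c = (rx - rx.mean()) / rx.std()
    ry_c = (ry - ry.mean()) / ry.std()
    n = len(rx)
    hits = 0
    for _ in range(n_permutations):
        r = float(rx_c @ ry_c[rng.permutation(n)]) / n
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return SpearmanResult(rho, float(p), len(pairs))


def monthly_trend(weekly_summaries: Sequence[PeriodSummary],
                  months: Sequence[str]) -> dict[str, dict[str, float]]:
    """Collapse weekly period means into calendar-month means; weeks
    assigned the same month label (e.g. the weeks straddling an order
    date, merged into one March) are averaged together."""
    if len(weekly_summaries) != len(months):
        raise ValueError("one month label per weekly summary required")
    out: dict[str, dict[str, list[float]]] = {}
    for s, m in zip(weekly_summaries, months):
        if np.isnan(s.mean_kl):
            continue
        d = out.setdefault(m, {"kl": [], "js": [], "jaccard": []})
        d["kl"].append(s.mean_kl)
        d["js"].append(s.mean_js)
        d["jaccard"].append(s.mean_jaccard)
    return {
        m: {k: float(np.mean(v)) for k, v in d.items()}
        for m, d in out.items()
    }
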