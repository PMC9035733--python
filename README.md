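# depsignal

Detection of depression-relevant signals in keyword-collected social-media
text. The package implements a complete analysis pipeline for
epidemiological text mining: corpus construction and cleaning, four
families of document features (psycholinguistic category proportions, a
fused depression-vocabulary family, bi-gram TF-IDF, and latent topics),
screening of topics for depression-indicative vocabulary, topic-overlap
similarity analysis across time periods, and temporal prediction of a
per-user depression signal. It is written for researchers studying
population mental-health signals in platforms like Twitter/X, where the
raw corpora usually cannot be redistributed: a first-class synthetic-data
generator plants known topic and vocabulary structure so that every stage
of the pipeline is testable end to end without any download.

## The method

**Corpus construction.** Tweets bearing a collection keyword or hashtag
(default: `COVID`, `coronavirus`, `#StayAtHome`, `#StayHome`) are
retained; exact duplicates, bare retweets (`RT @user` with no added
text), and keyword-only tweets are dropped; tweets pairing a pandemic
term with a mental-health term (`mental health`, `depression`) are
removed, on the assumption that such tweets convey information rather
than personal experience. Links are stripped, emojis kept; stopwords are
removed but pronouns retained (first-person pronoun use is a known
depression marker); users need at least five surviving tweets. The corpus
is sliced into consecutive half-open one-week bins.

**Features.** Per tweet *t* and bi-gram *w*:

```
tfidf(w, t) = (1 + ln n_wt) · ln(T / T_w)
```

with `n_wt` the bi-gram count in the tweet, `T` the number of tweets and
`T_w` the number of tweets containing the bi-gram (natural log,
unsmoothed). The LIWC-style family measures the token proportion of every
psychological-processes and personal-concerns subcategory of a
`.dic`-format dictionary plus the first-person-pronoun proportion. The
PLUS family fuses a psychiatric glossary, a word–emotion lexicon and a
psycholinguistic norms table: glossary tokens tagged *joy* are discarded,
each norm property is averaged over the survivors, and their density
(survivors / tokens) is appended. Topic features are the document–topic
mixtures θ of a K-topic LDA model (default K = 50, symmetric priors
α = β = 0.01) fitted by collapsed Gibbs sampling with conditionals

```
p(z_i = k | z_-i, w) ∝ (n_dk + α)(n_kw + β) / (n_k + Vβ).
```

**Topic screening and similarity.** Each topic is summarised by its
top-15 highest-probability words and marked depression-indicative when at
least *m* = 2 of them are non-joy glossary words or fall into
negative-emotion categories (a reproducible stand-in for expert topic
validation). For similarity analysis each topic keeps its top-ten
depression-related words; synonym variants are harmonized to canonical
forms. Topic pairs within a period are compared by KL divergence
`KL(P‖Q) = Σ pᵢ ln(pᵢ/qᵢ)` (union support, additive-ε smoothing), by the
symmetrized mixture divergence `½KL(P‖M) + ½KL(Q‖M)` with `M = (P+Q)/2`
(bounded by ln 2), and by the Jaccard similarity `|A∩B| / |A∪B|` of the
harmonized word sets. A Spearman rank correlation with a permutation
p-value relates the set-based and distribution-based metrics per period.

**Prediction.** A continuous per-user depression-signal score (default:
mean depression-word density; injectable) is regressed on any feature
combination by elastic net under stratified 10-fold cross-validation,
scored by the Pearson r of pooled out-of-fold predictions. For temporal
prediction, features from the first through the penultimate week train an
SVM (RBF, λ = 0.0001 as C = 1/λ, γ = 0.5), logistic regression, or random
forest (500 trees, depth 3, 30 features per split) to predict the binary
above/below-median signal in the last week, scored by the positive-class
F-1.

## Worked example

Compare topic-vocabulary overlap between a low-overlap ("before") and a
high-overlap ("during") synthetic regime:

```python
from datetime import timedelta
from depsignal import (SyntheticSpec, generate_corpus, generate_lexicons,
                       FilterConfig, preprocess_corpus, fit_lda, screen_all,
                       period_similarity, cross_metric_spearman)

for regime in ("low", "high"):
    spec = SyntheticSpec(n_users=30, tweets_per_user=5, n_weeks=2,
                         overlap_regime=regime, seed=1)
    tweets, truth = generate_corpus(spec)
    bundle = generate_lexicons(spec)
    cfg = FilterConfig(period_start=spec.period_start,
                       period_end=max(t.created_at for t in tweets)
                       + timedelta(seconds=1), min_tweets_per_user=1)
    clean, report = preprocess_corpus(tweets, cfg)
    model = fit_lda(clean, K=4, alpha=0.01, beta=0.01, n_iter=100, seed=2)
    screened = screen_all(model, bundle, m=2)
    pairs, summary = period_similarity(screened, bundle, period_id=regime)
    rho = cross_metric_spearman(pairs, seed=3)
    print(f"{regime:>4}: {summary.n_pairs} topic pairs | "
          f"mean Jaccard {summary.mean_jaccard:.3f} | "
          f"mean JS {summary.mean_js:.3f} | mean KL {summary.mean_kl:.2f} | "
          f"rho {rho.rho:.3f} (p={rho.p_value:.4f})")
```

Output:

```
 low: 6 topic pairs | mean Jaccard 0.024 | mean JS 0.674 | mean KL 12.03 | rho 0.674 (p=0.1637)
high: 6 topic pairs | mean Jaccard 0.094 | mean JS 0.586 | mean KL 9.93 | rho 0.812 (p=0.0625)
```

In the high-overlap regime, where the planted topics share most of the
depression vocabulary, the depression-related top words of different
fitted topics overlap more (higher Jaccard) and their probability
distributions are closer (lower JS and KL divergence) — the qualitative
signature of recurring depression vocabulary across topics. The Spearman
ρ shows the set-based and distribution-based metrics ranking topic pairs
consistently.

The same analysis, end to end with prediction and participation trends:

```sh
depsignal run --out demo_run --seed 7
```

writes a cleaned corpus, feature matrices, top-word tables, screening
results, weekly/monthly similarity reports, regression and classification
tables, participation trends and a manifest to `demo_run/`. Individual
stages are available as `depsignal synth | preprocess | features | lda`.

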