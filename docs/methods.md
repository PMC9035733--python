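# Methods

This note documents the models and procedures implemented in `depsignal`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data experiments do and do not establish.

## Scope and data model

The package analyses keyword-collected short-text corpora: one JSONL
record per post with an id, a user id, a UTC timestamp, the raw text and
a language tag. All analysis operates on two levels — per document
(tweet) and per user (mean of the user's document features). Because real
corpora of this kind are generally not redistributable, the package ships
a generator that produces corpora with *known* topic and vocabulary
structure; all quantitative claims in the test suite are claims about
recovery of that planted structure.

## Corpus construction

Filters run in a fixed order: language (en/fr; non-English text passes
through an injectable translation hook whose default is the identity —
no external translation service is bundled), keyword retention, duplicate
and bare-retweet removal, pandemic×mental-health co-occurrence removal,
link/mention stripping, tokenization, empty-document removal, and the
minimum-posting-history rule. Design choices worth stating:

* **Duplicates** are exact matches after case-folding and whitespace
  collapse; near-duplicate detection is deliberately out of scope.
  Retweets are recognised purely by a leading `RT @` prefix.
* **Stopwords** come from a compact packaged function-word list from
  which all personal pronouns are removed at config load, so pronoun
  retention cannot be configured away by accident. No named third-party
  stopword list is shipped.
* **Collection keywords are dropped at tokenization** (configurable). A
  keyword-collected corpus contains its keyword in essentially every
  document; as a token it is pure collection artifact, carries no
  content, and would otherwise occupy a top-word slot in every topic.
* **Weekly bins** are half-open `[start + 7i d, start + 7(i+1) d)` so no
  post is double-counted; empty bins are preserved to keep week indices
  calendar-aligned.
* The bigram phrase `mental health` is matched on normalized text, other
  exclusion terms as whole tokens, all case-insensitively.

## Feature families

* **bigram** — adjacent-token bi-grams after stopword removal
  (post-filter adjacency, mirroring the pipeline order), weighted
  `(1 + ln n_wt)·ln(T/T_w)`. Natural log throughout; the base only
  rescales columns and is irrelevant to the rank-based and linear models
  downstream. No smoothing: a bi-gram in every tweet weighs 0 by
  construction. Vocabulary pruning `min_df = 2` bounds the matrix width.
* **liwc** — proportions over a percent-delimited `.dic` category
  dictionary (trailing `*` = prefix match). Category names are namespaced
  `group:name` with groups `lingdim`, `psych`, `personal`; feature
  vectors cover every psych/personal subcategory plus only the
  first-person-pronoun proportion from the linguistic dimensions. The
  reader supports the standard dialect, but only a mock dictionary is
  packaged — no proprietary content ships with the code.
* **plus** — glossary ∩ tokens, minus words tagged *joy* in the emotion
  lexicon; per-property mean of the norm scores over survivors plus a
  density feature. Glossary words *absent* from the emotion lexicon are
  kept: absence of an emotion tag is not evidence of joy.
* **lda** — document–topic mixtures from the collapsed Gibbs sampler
  below; unseen documents are folded in with 50 fixed-φ sweeps, and an
  all-out-of-vocabulary document falls back to the uniform prior 1/K.

## Topic model

LDA is fitted by collapsed Gibbs sampling: `n_iter` full sweeps (default
500; no convergence test is applied) from a seeded random assignment,
after which φ and θ are read off the final count tables with Dirichlet
smoothing. Defaults K = 50 and α = β = 0.01 are the package's standard
analysis configuration. Determinism is guaranteed given the seed; the
per-sweep uniform variates are pre-drawn so the sampler's arithmetic is
reproducible across platforms. Correctness is checked three ways: the
token conditionals against an independent gamma-function evaluation of
the collapsed Dirichlet–multinomial joint (tolerance 1e-12), count-table
conservation after every sweep, and planted-topic recovery (per-topic
cosine ≥ 0.8 on a well-separated two-topic instance, cross-checked
against an independent variational implementation).

**Screening.** A topic is depression-indicative when at least *m* = 2 of
its top-15 words are non-joy glossary words, or at least *m* fall in
negative-emotion/sadness categories. This is a reproducible proxy for
expert validation of topics; *m* is configurable. "Engagement" with a
topic — nowhere standardised in this literature — is operationalized as
some tweet of the user having topic weight ≥ 0.2 (configurable).

## Similarity analysis

Each retained topic keeps its ≤ 10 highest-probability glossary words
(joy-tagged excluded) from the top 15. Synonym harmonization maps variant
spellings to canonical forms on both sides of a pair and merges the
probability mass of collapsing variants; the synonym map must be acyclic.
KL divergence needs a shared support: the union of the two retained sets
is used, probabilities renormalized, with additive smoothing ε = 1e-6 —
KL is infinite on disjoint supports, and partially overlapping topic
vocabularies are the norm here. Both the symmetrized mixture divergence
(bounded by ln 2) and the set-based Jaccard similarity are reported side
by side; period averages use the symmetrized KL mean `(KL_ab + KL_ba)/2`
since neither direction is privileged. The cross-metric Spearman ρ
correlates Jaccard against the *negated* divergence so that "more
similar" aligns on both axes; its p-value comes from pair-label
permutation (default 10,000 draws, seeded), chosen as assumption-free
given the small and dependent pair samples. Monthly trends average the
weekly period means; weeks straddling a policy-order date can be merged
under one month label by the caller.

## Prediction

The regression target is the central under-specification of this style
of analysis: a "depression signal" has no agreed operational definition.
The package's default — the user's mean depression-word density — is
declared, documented and injectable; synthetic recovery experiments
substitute the generator's planted signal instead. Note the default is
itself derived from the plus family, so regressions that include that
family are partly circular; this is intentional transparency, not a
hidden leak, and feature-combination comparisons should be read
accordingly.

Elastic net uses `l1_ratio` 0.5 and a logarithmic penalty grid over
1e-4…1e1; continuous targets are stratified by quantile bins (default 5,
shrunk automatically so every bin spans all folds) for 10-fold CV, the
penalty is selected per outer fold by inner 3-fold R², and the reported
Pearson r is computed on pooled out-of-fold predictions (pooling, rather
than averaging per-fold r, keeps small folds from dominating).

Classification labels are the above/below-median signal with the median
taken over the training weeks — a median split guarantees balanced
classes and a determinate positive class. The SVM regularization
parameter λ is applied under the inverse-regularization convention
C = 1/λ (library conventions differ; this one is stated explicitly), the
RBF γ literally, and the random forest's "30 features" as the maximum
features considered per split, capped by the actual feature count.

## Synthetic generator

The generator is the package's study-conditions definition, not a tuning
dial. Users each post `tweets_per_user ≥ 5` documents assigned
round-robin to `n_weeks` weeks, timestamps uniform within the week
(ISO-8601 UTC). Documents are drawn from a Dirichlet–multinomial process
with `K_true` planted topics; each topic concentrates on its own block of
general vocabulary (Dirichlet concentration 0.5 on block members) plus
its depression words (concentration 1.0, so they surface among top
words), over a `beta_true = 0.01` floor. A fraction
`depression_vocab_fraction` (default 0.15) of the vocabulary is the
depression glossary; `overlap_level` of it is shared across all topics
and the remainder split near-disjointly — `low` regime 0.1 ("before"),
`high` regime 0.8 ("during"). Document mixtures are
Dirichlet(`alpha_true` = 0.08), giving realistically sparse per-document
topic usage; document lengths are 5 + Poisson(5), so no empty document is
ever emitted. The per-user signal is the planted linear function of the
user's mean topic mixture (default coefficients linearly spaced over
[1, −1]) plus Gaussian noise (`noise_sd` = 0.05); binary labels are the
median split. Words are synthetic tokens (`w0001`, …): set and count
semantics are preserved without shipping clinical vocabulary. A stated
10% of glossary words are tagged *joy* so the discard rule is always
exercised, and every tweet text is prefixed with a planted collection
hashtag so the keyword filter operates as it would on a keyword-collected
corpus.

What the generator does **not** emulate: real platform language (slang,
spelling variation, code-switching, hashtag culture beyond the planted
tag), user heterogeneity in activity level, bursty posting, bots, or
geolocation. Passing tests therefore establish that the pipeline's
machinery is correct and that its measures separate regimes whose
difference is the planted vocabulary overlap — they do not establish
clinical validity of any feature family on real social-media text.

## Problem sizes and numerical choices

Test and demo experiments run at desk scale by design: tens of users,
hundreds of documents, K between 2 and 8, 40–150 Gibbs sweeps — large
enough for the planted structure to be recoverable, small enough that
the full suite and the pipeline demo execute in minutes on one CPU.
Tolerances: distribution normalization 1e-9; exact-formula oracles
1e-12; elastic-net-vs-OLS comparison 1e-6 at vanishing penalty. Ties in
top-word ranking break lexicographically for determinism. Degenerate
inputs are defined rather than left to chance: both-empty Jaccard is 0,
constant inputs to the rank correlation return a flagged null, a
single-class training set and a constant regression target raise errors.

## Known limitations

* The screening rule is a lexicon heuristic; it inherits every bias of
  the glossary and emotion lexicon supplied.
* KL values depend visibly on the smoothing ε when supports barely
  overlap; compare KL only across runs with identical ε.
* The default regression target's partial circularity (above) means
  absolute r values for plus-containing combinations overstate what an
  independent clinical outcome would yield.
* Weekly topic models are fitted independently per week; topic indices
  are not aligned across weeks, so similarity is within-period by
  construction.
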