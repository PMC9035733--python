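"""Psycholinguistic and bi-gram feature families.

Three of the four feature families live here:

* **bigram** — adjacent-token bi-grams weighted by a sublinear TF-IDF,
  ``(1 + ln n_wt) * ln(T / T_w)``, where ``n_wt`` is the bi-gram count in
  tweet ``t``, ``T`` the number of tweets and ``T_w`` the number of tweets
  containing the bi-gram.  No smoothing: a bi-gram present in every tweet
  gets weight 0.
* **liwc** — proportions of tokens matching a LIWC-style category
  dictionary: every psychological-processes and personal-concerns
  subcategory, and from the linguistic dimensions only the first-person
  pronoun proportion.
* **plus** — a fused depression-vocabulary family: tokens found in a
  psychiatric glossary are screened against a word–emotion lexicon (words
  tagged "joy" are discarded), and each psycholinguistic-norm property is
  averaged over the surviving words; a depression-word density feature
  (surviving words / tokens) is appended.

The fourth family (lda) is produced by :mod:`depsignal.lda`; matrices from
all families are combined with :func:`assemble`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .preprocess import Tweet

FIRSTPERSON_CATEGORY = "lingdim:firstperson"
GROUP_LINGDIM = "lingdim"
GROUP_PSYCH = "psych"
GROUP_PERSONAL = "personal"


# ---------------------------------------------------------------------------
# Lexicon bundle

@dataclass
class Category:
    """One dictionary category: exact entries plus prefix entries
    (a trailing ``*`` in the source file marks a prefix)."""

    exact: frozenset
    prefixes: tuple = ()

    def matches(self, token: str) -> bool:
        return token in self.exact or any(token.startswith(p) for p in self.prefixes)


@dataclass
class LexiconBundle:
    """The lexicons driving the liwc and plus families.

    ``category_dict`` keys are namespaced ``group:name`` where group is one
    of ``lingdim``, ``psych``, ``personal``; ``emotion_map`` values are
    subsets of the eight basic emotions plus the two sentiment poles;
    ``norms`` maps words to real-valued psycholinguistic properties;
    ``synonyms`` maps variant spellings to canonical forms.
    """

    category_dict: dict[str, Category]
    glossary: frozenset
    emotion_map: dict[str, frozenset]
    norms: dict[str, dict[str, float]]
    synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.glossary = frozenset(self.glossary)
        for w, c in self.synonyms.items():
            seen = {w}
            while c in self.synonyms:  # canonical forms must not chain back
                c = self.synonyms[c]
                if c in seen:
                    raise ValueError(f"cyclic synonym map at {w!r}")
                seen.add(c)

    @property
    def norm_properties(self) -> list[str]:
        props: list[str] = []
        for scores in self.norms.values():
            for p in scores:
                if p not in props:
                    props.append(p)
        return props

    def liwc_feature_names(self) -> list[str]:
        names = ["liwc:firstperson"]
        for cat in self.category_dict:
            grp = cat.split(":", 1)[0]
            if grp in (GROUP_PSYCH, GROUP_PERSONAL):
                names.append("liwc:" + cat.split(":", 1)[1])
        return names

    def plus_feature_names(self) -> list[str]:
        return ["plus:" + p for p in self.norm_properties] + ["plus:density"]

    def glossary_nonjoy(self) -> frozenset:
        """Glossary words not tagged joy (unmapped words kept)."""
        return frozenset(
            w for w in self.glossary if "joy" not in self.emotion_map.get(w, frozenset())
        )

    # -- serialization ------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_dic(self.category_dict, d / "categories.dic")
        (d / "glossary.txt").write_text("\n".join(sorted(self.glossary)) + "\n")
        with open(d / "emotions.tsv", "w") as fh:
            for w in sorted(self.emotion_map):
                for emo in sorted(self.emotion_map[w]):
                    fh.write(f"{w}\t{emo}\t1\n")
        props = self.norm_properties
        with open(d / "norms.csv", "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["word"] + props)
            for w in sorted(self.norms):
                wr.writerow([w] + [self.norms[w].get(p, "") for p in props])
        with open(d / "synonyms.tsv", "w") as fh:
            for w in sorted(self.synonyms):
                fh.write(f"{w}\t{self.synonyms[w]}\n")

    @classmethod
    def load(cls, directory) -> "LexiconBundle":
        d = Path(directory)
        cats = read_dic(d / "categories.dic")
        glossary = frozenset(
            w for w in (d / "glossary.txt").read_text().split() if w
        ) if (d / "glossary.txt").exists() else frozenset()
        emotion: dict[str, set] = {}
        if (d / "emotions.tsv").exists():
            for line in (d / "emotions.tsv").read_text().splitlines():
                if not line.strip():
                    continue
                w, emo, flag = line.split("\t")
                if flag.strip() == "1":
                    emotion.setdefault(w, set()).add(emo)
        norms: dict[str, dict[str, float]] = {}
        if (d / "norms.csv").exists():
            with open(d / "norms.csv", newline="") as fh:
                for row in csv.DictReader(fh):
                    w = row.pop("word")
                    norms[w] = {k: float(v) for k, v in row.items() if v != ""}
        synonyms: dict[str, str] = {}
        if (d / "synonyms.tsv").exists():
            for line in (d / "synonyms.tsv").read_text().splitlines():
                if line.strip():
                    w, c = line.split("\t")
                    synonyms[w] = c
        return cls(
            category_dict=cats,
            glossary=glossary,
            emotion_map={w: frozenset(v) for w, v in emotion.items()},
            norms=norms,
            synonyms=synonyms,
        )


def read_dic(path) -> dict[str, Category]:
    """Read a percent-delimited category dictionary (LIWC .dic dialect):
    a ``%``-fenced header of ``id<TAB>name`` lines, then ``word<TAB>ids``
    lines; a trailing ``*`` on a word marks prefix matching."""
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    names: dict[str, str] = {}
    in_header = False
    exact: dict[str, set] = {}
    prefixes: dict[str, set] = {}
    for line in it:
        s = line.strip()
        if not s:
            continue
        if s == "%":
            in_header = not in_header
            continue
        parts = s.split("\t")
        if in_header:
            names[parts[0]] = parts[1]
        else:
            word, ids = parts[0], parts[1:]
            for cid in ids:
                cat = names[cid]
                if word.endswith("*"):
                    prefixes.setdefault(cat, set()).add(word[:-1])
                else:
                    exact.setdefault(cat, set()).add(word)
    return {
        name: Category(
            exact=frozenset(exact.get(name, ())),
            prefixes=tuple(sorted(prefixes.get(name, ()))),
        )
        for name in names.values()
    }


def write_dic(cats: Mapping[str, Category], path) -> None:
    with open(path, "w") as fh:
        fh.write("%\n")
        ids = {name: str(i + 1) for i, name in enumerate(cats)}
        for name, cid in ids.items():
            fh.write(f"{cid}\t{name}\n")
        fh.write("%\n")
        entries: dict[str, list[str]] = {}
        for name, cat in cats.items():
            for w in cat.exact:
                entries.setdefault(w, []).append(ids[name])
            for p in cat.prefixes:
                entries.setdefault(p + "*", []).append(ids[name])
        for w in sorted(entries):
            fh.write(w + "\t" + "\t".join(sorted(entries[w], key=int)) + "\n")


# ---------------------------------------------------------------------------
# Feature matrix container

@dataclass
class FeatureMatrix:
    """Named feature columns over an ordered set of document or user rows."""

    row_ids: list[str]
    column_names: list[str]
    values: np.ndarray
    family_slices: dict[str, slice] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.column_names)):
            raise ValueError(
                f"shape {self.values.shape} != ({len(self.row_ids)}, {len(self.column_names)})"
            )
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("duplicate column names")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains NaN")
        if not self.family_slices:
            fams: dict[str, list[int]] = {}
            for j, c in enumerate(self.column_names):
                fams.setdefault(c.split(":", 1)[0], []).append(j)
            self.family_slices = {
                f: slice(idx[0], idx[-1] + 1)
                for f, idx in fams.items()
                if idx == list(range(idx[0], idx[-1] + 1))
            }

    @property
    def shape(self):
        return self.values.shape

    def family(self, name: str) -> "FeatureMatrix":
        if name not in self.family_slices:
            raise KeyError(f"no feature family {name!r}; have {sorted(self.family_slices)}")
        sl = self.family_slices[name]
        return FeatureMatrix(
            row_ids=list(self.row_ids),
            column_names=self.column_names[sl],
            values=self.values[:, sl].copy(),
            family_slices={name: slice(0, sl.stop - sl.start)},
        )

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.row_ids, columns=self.column_names)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="row_id")


def assemble(features: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of feature families sharing row ids."""
    if not features:
        raise ValueError("no feature matrices to assemble")
    base = features[0].row_ids
    for fm in features[1:]:
        if fm.row_ids != base:
            bad = set(fm.row_ids) ^ set(base)
            raise ValueError(f"row id mismatch; offending ids (sample): {sorted(bad)[:5]}")
    names: list[str] = []
    slices: dict[str, slice] = {}
    mats = []
    off = 0
    for fm in features:
        for fam, sl in fm.family_slices.items():
            if fam in slices:
                raise ValueError(f"duplicate family {fam!r}")
            slices[fam] = slice(off + sl.start, off + sl.stop)
        names.extend(fm.column_names)
        mats.append(fm.values)
        off += len(fm.column_names)
    return FeatureMatrix(list(base), names, np.hstack(mats), slices)


# ---------------------------------------------------------------------------
# Bi-gram TF-IDF

@dataclass
class TfIdfStats:
    """Fitted corpus statistics for the bi-gram TF-IDF weighting."""

    T: int
    T_w: dict[str, int]
    vocab: list[str]

    def weight(self, n_wt: int, w: str) -> float:
        if n_wt <= 0:
            return 0.0
        return (1.0 + math.log(n_wt)) * math.log(self.T / self.T_w[w])


def _bigrams(tokens: Sequence[str]) -> list[str]:
    return [tokens[i] + " " + tokens[i + 1] for i in range(len(tokens) - 1)]


def tfidf_bigrams(corpus: Sequence[Tweet], min_df: int = 2,
                  stats: TfIdfStats | None = None) -> tuple[FeatureMatrix, TfIdfStats]:
    """Adjacent-token bi-gram matrix with sublinear-TF, unsmoothed-IDF
    weights.

    The vocabulary keeps bi-grams occurring in at least ``min_df`` tweets.
    Passing fitted ``stats`` re-applies a previous fit to new tweets
    (unknown bi-grams ignored).
    """
    if not corpus:
        raise ValueError("empty corpus")
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    doc_bigrams = []
    for t in corpus:
        if not t.tokens:
            raise ValueError(f"tweet {t.id} has no tokens; tokenize first")
        doc_bigrams.append(_bigrams(t.tokens))
    if stats is None:
        df: dict[str, int] = {}
        for bgs in doc_bigrams:
            for w in set(bgs):
                df[w] = df.get(w, 0) + 1
        vocab = sorted(w for w, c in df.items() if c >= min_df)
        stats = TfIdfStats(T=len(corpus), T_w={w: df[w] for w in vocab}, vocab=vocab)
    index = {w: j for j, w in enumerate(stats.vocab)}
    X = np.zeros((len(corpus), len(stats.vocab)))
    for i, bgs in enumerate(doc_bigrams):
        counts: dict[str, int] = {}
        for w in bgs:
            if w in index:
                counts[w] = counts.get(w, 0) + 1
        for w, n in counts.items():
            X[i, index[w]] = stats.weight(n, w)
    fm = FeatureMatrix(
        row_ids=[t.id for t in corpus],
        column_names=["bigram:" + w for w in stats.vocab],
        values=X,
        family_slices={"bigram": slice(0, len(stats.vocab))},
    )
    return fm, stats


# ---------------------------------------------------------------------------
# LIWC-style category proportions

def liwc_features(tweet: Tweet, bundle: LexiconBundle) -> np.ndarray:
    """Category-proportion vector: first-person pronoun proportion, then one
    proportion per psychological-processes / personal-concerns subcategory.

    A token-less tweet yields a zero vector (logged by the caller's report).
    """
    names = bundle.liwc_feature_names()
    vec = np.zeros(len(names))
    n = len(tweet.tokens)
    if n == 0:
        return vec
    j = 0
    fp = bundle.category_dict.get(FIRSTPERSON_CATEGORY)
    if fp is not None:
        vec[0] = sum(fp.matches(t) for t in tweet.tokens) / n
    j = 1
    for cat, entry in bundle.category_dict.items():
        grp = cat.split(":", 1)[0]
        if grp not in (GROUP_PSYCH, GROUP_PERSONAL):
            continue
        vec[j] = sum(entry.matches(t) for t in tweet.tokens) / n
        j += 1
    return vec


def liwc_matrix(corpus: Sequence[Tweet], bundle: LexiconBundle) -> FeatureMatrix:
    names = bundle.liwc_feature_names()
    X = np.vstack([liwc_features(t, bundle) for t in corpus]) if corpus else np.zeros((0, len(names)))
    return FeatureMatrix([t.id for t in corpus], names, X,
                         {"liwc": slice(0, len(names))})


# ---------------------------------------------------------------------------
# PLUS: glossary x emotion-screen x norms fusion

def plus_features(tweet: Tweet, bundle: LexiconBundle) -> np.ndarray:
    """Averaged norm scores over glossary tokens surviving the joy screen,
    plus the surviving-word density.

    Glossary words absent from the emotion lexicon are kept: absence of an
    emotion tag is not evidence of joy.
    """
    props = bundle.norm_properties
    vec = np.zeros(len(props) + 1)
    if not tweet.tokens:
        return vec
    survivors = [t for t in tweet.tokens
                 if t in bundle.glossary
                 and "joy" not in bundle.emotion_map.get(t, frozenset())]
    if not survivors:
        return vec
    for j, p in enumerate(props):
        scores = [bundle.norms[w][p] for w in survivors
                  if w in bundle.norms and p in bundle.norms[w]]
        if scores:
            vec[j] = float(np.mean(scores))
    vec[-1] = len(survivors) / len(tweet.tokens)
    return vec


def plus_matrix(corpus: Sequence[Tweet], bundle: LexiconBundle) -> FeatureMatrix:
    names = bundle.plus_feature_names()
    X = np.vstack([plus_features(t, bundle) for t in corpus]) if corpus else np.zeros((0, len(names)))
    return FeatureMatrix([t.id for t in corpus], names, X,
                         {"plus": slice(0, len(names))})


# ---------------------------------------------------------------------------
# User-level aggregation

def aggregate_by_user(doc_matrix: FeatureMatrix,
                      user_map: Mapping[str, str]) -> FeatureMatrix:
    """Per-user mean of document rows; users ordered by first appearance."""
    users: list[str] = []
    rows_of: dict[str, list[int]] = {}
    for i, rid in enumerate(doc_matrix.row_ids):
        if rid not in user_map:
            raise KeyError(f"row id {rid!r} has no user mapping")
        u = user_map[rid]
        if u not in rows_of:
            users.append(u)
            rows_of[u] = []
        rows_of[u].append(i)
    X = np.vstack([doc_matrix.values[rows_of[u]].mean(axis=0) for u in users])
    return FeatureMatrix(users, list(doc_matrix.column_names), X,
                         dict(doc_matrix.family_slices))


def user_map_of(corpus: Iterable[Tweet]) -> dict[str, str]:
    return {t.id: t.user_id for t in corpus}
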