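"""Corpus construction and cleaning for keyword-collected tweet streams.

The filters implement the corpus rules used throughout the package: keep
tweets bearing a collection keyword or hashtag, drop exact duplicates and
bare retweets, drop tweets pairing a pandemic term with a mental-health
term, strip links and mentions while keeping emojis, tokenize with stopword
removal that retains pronouns, require a minimum posting history per user,
and slice the surviving corpus into consecutive one-week bins.

All filters are order-preserving and idempotent; none ever adds a tweet.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Callable, Iterable, Sequence

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Tweet record

@dataclass
class Tweet:
    """One timestamped user post.

    ``tokens`` stays empty until :func:`tokenize` is applied; filters that
    act on raw text must run before tokenization.
    """

    id: str
    user_id: str
    created_at: datetime
    text: str
    lang: str = "en"
    tokens: list[str] = field(default_factory=list)

    @classmethod
    def from_json(cls, line: str) -> "Tweet":
        d = json.loads(line)
        return cls(
            id=str(d["id"]),
            user_id=str(d["user_id"]),
            created_at=parse_timestamp(d["created_at"]),
            text=d["text"],
            lang=d.get("lang", "en"),
            tokens=list(d.get("tokens", [])),
        )

    def to_json(self) -> str:
        d = {
            "id": self.id,
            "user_id": self.user_id,
            "created_at": self.created_at.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "text": self.text,
            "lang": self.lang,
        }
        if self.tokens:
            d["tokens"] = self.tokens
        return json.dumps(d, ensure_ascii=False)


TweetCollection = list  # list[Tweet]; plain list keeps filters order-preserving


def parse_timestamp(s: str | datetime) -> datetime:
    if isinstance(s, datetime):
        return s if s.tzinfo else s.replace(tzinfo=timezone.utc)
    dt = datetime.fromisoformat(s.replace("Z", "+00:00"))
    return dt if dt.tzinfo else dt.replace(tzinfo=timezone.utc)


def read_jsonl(path) -> list[Tweet]:
    with open(path, encoding="utf-8") as fh:
        return [Tweet.from_json(line) for line in fh if line.strip()]


def write_jsonl(tweets: Iterable[Tweet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in tweets:
            fh.write(t.to_json() + "\n")


# ---------------------------------------------------------------------------
# Configuration

#: Personal pronouns always retained during stopword removal.  First-person
#: singular pronouns carry the self-attention signal the LIWC family scores.
PRONOUNS = frozenset(
    "i me my mine myself we us our ours ourselves you your yours yourself "
    "he him his himself she her hers herself it its itself they them their "
    "theirs themselves".split()
)

#: Compact English stopword list (function words only; no named source's
#: list is shipped).  Pronouns are removed from it at config load.
STOPWORDS = frozenset(
    "a an the and or but if then else when while of at by for with about "
    "against between into through during before after above below to from "
    "up down in out on off over under again further once here there all "
    "any both each few more most other some such no nor not only own same "
    "so than too very can will just should now is am are was were be been "
    "being have has had having do does did doing would could ought im ive "
    "dont doesnt didnt isnt arent wasnt werent wont wouldnt couldnt "
    "shouldnt cant as that this these those what which who whom because "
    "until".split()
)

DEFAULT_KEYWORDS = frozenset({"covid", "coronavirus", "#stayathome", "#stayhome"})
DEFAULT_EXCLUSION = (frozenset({"covid", "coronavirus"}),
                     frozenset({"mental health", "depression"}))


@dataclass
class FilterConfig:
    """Corpus-construction parameters.

    ``exclusion_pair`` is a (pandemic terms, mental-health terms) pair: a
    tweet containing at least one term from each side is dropped.  Terms on
    the mental-health side may be bigram phrases ("mental health").
    """

    keywords: frozenset = DEFAULT_KEYWORDS
    exclusion_pair: tuple = DEFAULT_EXCLUSION
    stopwords: frozenset = STOPWORDS
    pronouns_keep: frozenset = PRONOUNS
    min_tweets_per_user: int = 5
    period_start: datetime | None = None
    period_end: datetime | None = None
    week_length_days: int = 7
    languages: frozenset = frozenset({"en", "fr"})
    #: collection keywords are present in (nearly) every tweet by
    #: construction and carry no content; drop them at tokenization
    drop_keyword_tokens: bool = True

    def __post_init__(self):
        if self.min_tweets_per_user < 1:
            raise ValueError("min_tweets_per_user must be >= 1")
        # pronouns always survive stopword removal
        self.stopwords = frozenset(self.stopwords) - frozenset(self.pronouns_keep)
        self.keywords = frozenset(k.casefold() for k in self.keywords)
        if self.period_start is not None:
            self.period_start = parse_timestamp(self.period_start)
        if self.period_end is not None:
            self.period_end = parse_timestamp(self.period_end)


# ---------------------------------------------------------------------------
# Text patterns

_URL_RE = re.compile(r"""(?:https?://\S+|www\.\S+|\bt\.co/\S+|\bpic\.twitter\.com/\S+)""", re.I)
_MENTION_RE = re.compile(r"@\w+")
_MEDIA_RE = re.compile(r"\[(?:media|photo|video|image)\]", re.I)
_RT_RE = re.compile(r"^\s*rt\s+@\w+\s*:?\s*$", re.I)
_WS_RE = re.compile(r"\s+")

# Emoji / pictograph code-point ranges (misc symbols, dingbats, emoticons,
# transport, supplemental symbols, flags).
EMOJI_RE = re.compile(
    "["
    "\U0001F300-\U0001FAFF"
    "\U0001F1E6-\U0001F1FF"
    "☀-➿"
    "⬀-⯿"
    "️"
    "]"
)

_WORD_OR_EMOJI_RE = re.compile(
    r"#?[A-Za-zÀ-ɏ][A-Za-zÀ-ɏ0-9']*"
    r"|[" "\U0001F300-\U0001FAFF" "\U0001F1E6-\U0001F1FF" "☀-➿" "⬀-⯿" "]"
)


def _rough_tokens(text: str) -> list[str]:
    """Case-folded word/hashtag tokens of raw text (hashtag mark kept)."""
    return [m.group(0).casefold() for m in _WORD_OR_EMOJI_RE.finditer(text)]


# ---------------------------------------------------------------------------
# Filters

def filter_language(tweets: Sequence[Tweet], cfg: FilterConfig,
                    translate: Callable[[str], str] | None = None) -> list[Tweet]:
    """Keep tweets in an accepted language; pass non-English ones through
    ``translate`` (default: identity — no external translation service)."""
    out = []
    for t in tweets:
        if t.lang not in cfg.languages:
            continue
        if t.lang != "en" and translate is not None:
            t = replace(t, text=translate(t.text), lang="en")
        out.append(t)
    return out


def filter_keywords(tweets: Sequence[Tweet], cfg: FilterConfig) -> list[Tweet]:
    """Retain tweets whose text bears a collection keyword as a whole token
    or hashtag, case-insensitively."""
    if not cfg.keywords:
        raise ValueError("keyword set is empty; configure FilterConfig.keywords")
    bare = {k.lstrip("#") for k in cfg.keywords}
    out = []
    for t in tweets:
        toks = _rough_tokens(t.text)
        stripped = {tok.lstrip("#") for tok in toks}
        if stripped & bare:
            out.append(t)
    return out


def _normalized(text: str) -> str:
    return _WS_RE.sub(" ", text.casefold()).strip()


def drop_redundant(tweets: Sequence[Tweet], cfg: FilterConfig) -> list[Tweet]:
    """Drop exact duplicates (first occurrence kept), bare retweets
    ("RT @user" with no added text), and tweets whose tokens are only
    collection keywords."""
    bare_kw = {k.lstrip("#") for k in cfg.keywords}
    seen: set[str] = set()
    out = []
    for t in tweets:
        norm = _normalized(t.text)
        if norm in seen:
            continue
        if norm.startswith("rt @") and _RT_RE.match(norm):
            continue
        toks = {tok.lstrip("#") for tok in _rough_tokens(t.text)}
        if toks and toks <= bare_kw:
            continue
        seen.add(norm)
        out.append(t)
    return out


def drop_cooccurrence(tweets: Sequence[Tweet], cfg: FilterConfig) -> list[Tweet]:
    """Drop tweets pairing a pandemic term with a mental-health term
    (bigram phrases matched on normalized text)."""
    side_a, side_b = cfg.exclusion_pair

    def has_term(norm: str, toks: set, term: str) -> bool:
        term = term.casefold()
        if " " in term:
            return term in norm
        return term in toks

    out = []
    for t in tweets:
        norm = _normalized(t.text)
        toks = {tok.lstrip("#") for tok in _rough_tokens(t.text)}
        a = any(has_term(norm, toks, w) for w in side_a)
        b = any(has_term(norm, toks, w) for w in side_b)
        if not (a and b):
            out.append(t)
    return out


def clean_text(tweet: Tweet) -> Tweet:
    """Remove links, user mentions and media placeholders; keep emojis.
    Returns a new record; the input is not modified."""
    text = _URL_RE.sub(" ", tweet.text)
    text = _MENTION_RE.sub(" ", text)
    text = _MEDIA_RE.sub(" ", text)
    return replace(tweet, text=_WS_RE.sub(" ", text).strip())


def tokenize(tweet: Tweet, cfg: FilterConfig) -> Tweet:
    """Case-folded word and emoji tokens; stopwords dropped unless they are
    retained pronouns; hashtag marks stripped."""
    toks = []
    bare_kw = {k.lstrip("#") for k in cfg.keywords} if cfg.drop_keyword_tokens else set()
    for raw in _WORD_OR_EMOJI_RE.findall(tweet.text):
        tok = raw.casefold().lstrip("#")
        if not tok:
            continue
        if tok in cfg.stopwords and tok not in cfg.pronouns_keep:
            continue
        if tok in bare_kw:
            continue
        toks.append(tok)
    return replace(tweet, tokens=toks)


def filter_min_user_tweets(tweets: Sequence[Tweet], cfg: FilterConfig) -> list[Tweet]:
    """Retain tweets of users with at least ``min_tweets_per_user``
    surviving tweets."""
    counts: dict[str, int] = {}
    for t in tweets:
        counts[t.user_id] = counts.get(t.user_id, 0) + 1
    return [t for t in tweets if counts[t.user_id] >= cfg.min_tweets_per_user]


def slice_weekly(tweets: Sequence[Tweet], cfg: FilterConfig) -> list[list[Tweet]]:
    """Partition tweets into consecutive half-open bins
    [start + i*w, start + (i+1)*w) covering [period_start, period_end).

    Tweets outside the period are excluded (count logged); empty bins are
    preserved so week indices stay aligned with the calendar.
    """
    if cfg.period_start is None or cfg.period_end is None:
        raise ValueError("period_start and period_end must be set for weekly slicing")
    w = timedelta(days=cfg.week_length_days)
    span = cfg.period_end - cfg.period_start
    n_bins = int(-(-span.total_seconds() // w.total_seconds())) if span > timedelta(0) else 0
    bins: list[list[Tweet]] = [[] for _ in range(n_bins)]
    dropped = 0
    for t in tweets:
        if not (cfg.period_start <= t.created_at < cfg.period_end):
            dropped += 1
            continue
        i = int((t.created_at - cfg.period_start) // w)
        bins[i].append(t)
    if dropped:
        log.info("slice_weekly: excluded %d tweets outside the study period", dropped)
    return bins


def week_start(cfg: FilterConfig, i: int) -> datetime:
    return cfg.period_start + timedelta(days=i * cfg.week_length_days)


# ---------------------------------------------------------------------------
# Composed pipeline

def preprocess_corpus(tweets: Sequence[Tweet], cfg: FilterConfig,
                      translate: Callable[[str], str] | None = None,
                      apply_keyword_filter: bool = True,
                      ) -> tuple[list[Tweet], dict]:
    """Run the full filter chain, returning surviving tokenized tweets and a
    per-rule removal report."""
    report: dict[str, int] = {"input": len(tweets)}
    cur = filter_language(tweets, cfg, translate)
    report["removed_language"] = report["input"] - len(cur)
    if apply_keyword_filter:
        n = len(cur)
        cur = filter_keywords(cur, cfg)
        report["removed_no_keyword"] = n - len(cur)
    n = len(cur)
    cur = drop_redundant(cur, cfg)
    report["removed_redundant"] = n - len(cur)
    n = len(cur)
    cur = drop_cooccurrence(cur, cfg)
    report["removed_cooccurrence"] = n - len(cur)
    cur = [tokenize(clean_text(t), cfg) for t in cur]
    n = len(cur)
    cur = [t for t in cur if t.tokens]
    report["removed_empty_after_tokenize"] = n - len(cur)
    n = len(cur)
    cur = filter_min_user_tweets(cur, cfg)
    report["removed_min_user_tweets"] = n - len(cur)
    report["output"] = len(cur)
    report["distinct_users"] = len({t.user_id for t in cur})
    for rule, k in report.items():
        if rule.startswith("removed"):
            log.info("preprocess: %s = %d", rule, k)
    return cur, report
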