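from datetime import datetime, timedelta, timezone

import pytest

from depsignal import FilterConfig, SyntheticSpec, generate_corpus, generate_lexicons


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_users=20, tweets_per_user=5, n_weeks=3, vocab_size=200,
                         K_true=3, seed=42)


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    return generate_corpus(small_spec)


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return generate_lexicons(small_spec)


@pytest.fixture()
def filter_cfg(small_corpus):
    tweets, _ = small_corpus
    start = min(t.created_at for t in tweets).replace(hour=0, minute=0, second=0,
                                                      microsecond=0)
    end = max(t.created_at for t in tweets) + timedelta(seconds=1)
    return FilterConfig(period_start=start, period_end=end, min_tweets_per_user=1)


def make_tweet(id="t1", user="u1", text="hello", ts="2020-03-12T00:00:00Z",
               lang="en", tokens=()):
    from depsignal import Tweet
    from depsignal.preprocess import parse_timestamp

    return Tweet(id=id, user_id=user, created_at=parse_timestamp(ts), text=text,
                 lang=lang, tokens=list(tokens))


@pytest.fixture()
def mk_tweet():
    return make_tweet
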