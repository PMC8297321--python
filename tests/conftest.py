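import datetime

import pytest

from driftlex.lexicon import Lexicon, LexiconEntry
from driftlex.preprocess import ProcessedTweet


def mk_tweet(tid, day, lemmas, country="ES", tokens=None):
    """Build a ProcessedTweet directly (bypasses text processing)."""
    if isinstance(day, str):
        day = datetime.date.fromisoformat(day)
    return ProcessedTweet(
        id=tid,
        day=day,
        country_code=country,
        clean_text=" ".join(lemmas),
        tokens=tokens if tokens is not None else list(lemmas),
        lemmas=list(lemmas),
    )


@pytest.fixture
def small_lexicon():
    """bueno 0.8 / malo -0.6 / raro 0.2 — used by the hand-traced fixtures."""
    lex = Lexicon()
    lex.add(LexiconEntry("bueno", 0.8))
    lex.add(LexiconEntry("malo", -0.6))
    lex.add(LexiconEntry("raro", 0.2))
    return lex


@pytest.fixture
def two_day_batchset():
    """The hand-traceable 2-day stream (see test_engine for the trace)."""
    d1, d2 = "2020-03-01", "2020-03-02"
    day1 = [
        mk_tweet("t1", d1, ["bueno", "raro"]),
        mk_tweet("t2", d1, ["malo"]),
        mk_tweet("t3", d1, ["nuevo", "bueno"]),
        mk_tweet("t4", d1, ["nuevo", "malo", "malo"]),
    ]
    day2 = [
        mk_tweet("t5", d2, ["nuevo"]),
        mk_tweet("t6", d2, ["bueno", "nuevo"]),
    ]
    return day1, day2
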