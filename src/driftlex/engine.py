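"""Sentiment evaluation engine: per-tweet scoring, daily word-sentiment
updates by exponential smoothing, and new-word learning.

Per day d, each retained tweet is scored against the start-of-day lexicon
(the mean polarity over matched lemma occurrences).  Every lexicon word w
observed in n_w(d) >= 1 defined-score tweets is then pulled toward the mean
m_w(d) of those tweets' scores:

    s_w(d) = (1 - alpha) * s_w(d-1) + alpha * m_w(d)

Words without evidence keep their polarity.  After the update, lemmas absent
from the lexicon that appeared in enough defined-score tweets are learned at
the mean of those scores.  Scoring always precedes updating, so results are
invariant to tweet order within a day.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Iterable, Sequence

from .archive import Archive, SentimentRecord
from .lexicon import Lexicon, LexiconEntry
from .preprocess import ProcessedTweet


@dataclass(frozen=True)
class EngineConfig:
    """Engine knobs: smoothing weight, learning threshold, learning switch."""

    alpha: float = 0.3
    min_learn_occurrences: int = 2
    learn_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha {self.alpha} outside (0, 1]")
        if self.min_learn_occurrences < 1:
            raise ValueError("min_learn_occurrences must be >= 1")


@dataclass(frozen=True)
class TweetScore:
    """Score of one tweet: mean lexicon polarity over matched occurrences,
    or undefined (None) when no lemma matched."""

    tweet_id: str
    day: datetime.date
    score: float | None
    matched: tuple[str, ...]


@dataclass
class DailyBatch:
    """All tweets for one calendar day."""

    day: datetime.date
    tweets: list[ProcessedTweet]

    def __post_init__(self) -> None:
        for t in self.tweets:
            if t.day != self.day:
                raise ValueError(f"tweet {t.id} has day {t.day}, batch day {self.day}")


def score_tweet(lemmas: Sequence[str], lex: Lexicon, tweet_id: str = "",
                day: datetime.date | None = None) -> TweetScore:
    """Mean lexicon polarity over matched lemma occurrences (repeats counted
    per occurrence); undefined when nothing matches."""
    matched = [x for x in lemmas if x in lex]
    score = None
    if matched:
        score = sum(lex.polarity(x) for x in matched) / len(matched)
    return TweetScore(tweet_id=tweet_id, day=day, score=score, matched=tuple(matched))


def daily_update(
    batch: DailyBatch,
    lex: Lexicon,
    cfg: EngineConfig,
    country: str = "all",
) -> tuple[Lexicon, list[TweetScore], list[SentimentRecord]]:
    """Score a day's tweets against the start-of-day lexicon and update it.

    Returns the (mutated) lexicon, the per-tweet scores, and one
    :class:`SentimentRecord` per word with evidence on the day.  Records are
    emitted in sorted lemma order for determinism.
    """
    scores = [score_tweet(t.lemmas, lex, t.id, t.day) for t in batch.tweets]

    # Evidence: per lexicon word, scores of the distinct tweets containing it.
    evidence: dict[str, list[float]] = {}
    for sc in scores:
        if sc.score is None:
            continue
        for lemma in set(sc.matched):
            evidence.setdefault(lemma, []).append(sc.score)

    records: list[SentimentRecord] = []
    for lemma in sorted(evidence):
        tweet_scores = evidence[lemma]
        n = len(tweet_scores)
        # value-sorted summation keeps the mean bit-identical under any
        # within-day tweet permutation
        m = sum(sorted(tweet_scores)) / n
        entry = lex[lemma]
        s_new = (1.0 - cfg.alpha) * entry.polarity + cfg.alpha * m
        s_new = min(1.0, max(-1.0, s_new))  # guard float round-off at the rim
        entry.polarity = s_new
        entry.total_frequency += n
        records.append(
            SentimentRecord(
                lemma=lemma,
                day=batch.day,
                polarity_after=s_new,
                daily_mean=m,
                daily_count=n,
                country=country,
            )
        )
    return lex, scores, records


def learn_new_words(
    batch: DailyBatch,
    lex: Lexicon,
    cfg: EngineConfig,
    scores: list[TweetScore] | None = None,
) -> Lexicon:
    """Insert out-of-lexicon lemmas with enough defined-score evidence.

    A lemma absent from the lexicon appearing in at least
    ``cfg.min_learn_occurrences`` tweets with defined scores on the day is
    added with polarity equal to the mean of those tweets' scores
    (origin="learned").  Runs after :func:`daily_update`; when the scores
    computed there are passed in, they are reused instead of re-scoring.
    """
    if not cfg.learn_enabled:
        return lex
    if scores is None:
        scores = [score_tweet(t.lemmas, lex, t.id, t.day) for t in batch.tweets]
    candidate: dict[str, list[float]] = {}
    for sc, tweet in zip(scores, batch.tweets):
        if sc.score is None:
            continue
        for lemma in set(tweet.lemmas):
            if lemma not in lex:
                candidate.setdefault(lemma, []).append(sc.score)
    for lemma in sorted(candidate):
        tweet_scores = candidate[lemma]
        if len(tweet_scores) < cfg.min_learn_occurrences:
            continue
        polarity = sum(sorted(tweet_scores)) / len(tweet_scores)
        polarity = min(1.0, max(-1.0, polarity))
        lex.add(
            LexiconEntry(
                lemma=lemma,
                polarity=polarity,
                origin="learned",
                created_on=batch.day,
                total_frequency=len(tweet_scores),
            )
        )
    return lex


def run_stream(
    tweets: Iterable[ProcessedTweet],
    lex: Lexicon,
    cfg: EngineConfig,
    country: str = "all",
    archive: Archive | None = None,
) -> tuple[Archive, Lexicon]:
    """Process a multi-day stream: per day, score -> update -> learn.

    Days are processed in strictly increasing order (input is sorted by day
    internally; order within a day is irrelevant to the results).  Learned
    words participate in scoring from the following day onward.
    """
    if archive is None:
        archive = Archive()
    by_day: dict[datetime.date, list[ProcessedTweet]] = {}
    for t in tweets:
        by_day.setdefault(t.day, []).append(t)
    for day in sorted(by_day):
        batch = DailyBatch(day=day, tweets=by_day[day])
        lex, scores, records = daily_update(batch, lex, cfg, country=country)
        for rec in records:
            archive.append(rec)
        lex = learn_new_words(batch, lex, cfg, scores=scores)
    return archive, lex
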