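"""Three-stage keyword filtering (context -> topic -> country) and the
topic-by-country tweet count report."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .preprocess import ProcessedTweet, RawTweet, process, tokenize


@dataclass(frozen=True)
class RuleSet:
    """A named keyword set; each keyword is a phrase of normalized tokens."""

    name: str
    keywords: frozenset[tuple[str, ...]]

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"rule set {self.name!r} has no keywords")
        for phrase in self.keywords:
            if not phrase or any(not tok for tok in phrase):
                raise ValueError(f"rule set {self.name!r} has an empty phrase")

    @classmethod
    def from_phrases(cls, name: str, phrases: Iterable[str]) -> "RuleSet":
        """Build a rule set from raw keyword strings (tokenized/normalized)."""
        keywords = set()
        for phrase in phrases:
            toks = tuple(tokenize(phrase))
            if toks:
                keywords.add(toks)
        return cls(name=name, keywords=frozenset(keywords))


def matches(rule: RuleSet, tokens: Sequence[str]) -> bool:
    """True iff any keyword phrase occurs as a contiguous token subsequence.

    Matching is token-level: keyword "covid" does not match token
    "covidiota".
    """
    n = len(tokens)
    for phrase in rule.keywords:
        k = len(phrase)
        if k > n:
            continue
        for i in range(n - k + 1):
            if tuple(tokens[i : i + k]) == phrase:
                return True
    return False


def classify_topics(
    tweet: ProcessedTweet, topic_rules: Sequence[RuleSet], use_lemmas: bool = False
) -> set[str]:
    """All topic names whose rule set matches; a tweet may carry several."""
    toks = tweet.lemmas if use_lemmas else tweet.tokens
    return {rule.name for rule in topic_rules if matches(rule, toks)}


@dataclass
class CountsTable:
    """Topic-by-country retained-tweet counts with additive totals."""

    counts: dict[tuple[str, str], int]
    row_totals: dict[str, int]
    grand_total: int
    countries: list[str] = field(default_factory=list)
    topics: list[str] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("country," + ",".join(self.topics) + ",total\n")
            for c in self.countries:
                cells = [str(self.counts[(c, t)]) for t in self.topics]
                fh.write(f"{c}," + ",".join(cells) + f",{self.row_totals[c]}\n")
            fh.write(
                "total,"
                + ",".join(
                    str(sum(self.counts[(c, t)] for c in self.countries))
                    for t in self.topics
                )
                + f",{self.grand_total}\n"
            )


def report_counts(cells: Mapping[tuple[str, str], int]) -> CountsTable:
    """Assemble a :class:`CountsTable` from a (country, topic) -> count grid.

    Row totals are the per-country sums over topics; the grand total sums the
    rows.  Negative cells are rejected.
    """
    countries: list[str] = []
    topics: list[str] = []
    for country, topic in cells:
        if country not in countries:
            countries.append(country)
        if topic not in topics:
            topics.append(topic)
    counts: dict[tuple[str, str], int] = {}
    for c in countries:
        for t in topics:
            v = int(cells.get((c, t), 0))
            if v < 0:
                raise ValueError(f"negative count for ({c!r}, {t!r}): {v}")
            counts[(c, t)] = v
    row_totals = {c: sum(counts[(c, t)] for t in topics) for c in countries}
    return CountsTable(
        counts=counts,
        row_totals=row_totals,
        grand_total=sum(row_totals.values()),
        countries=countries,
        topics=topics,
    )


def filter_stream(
    raws: Iterable[RawTweet],
    context: RuleSet,
    topics: Sequence[RuleSet],
    countries: Iterable[str],
    stopwords: frozenset[str] | set[str] = frozenset(),
    use_lemmas: bool = False,
    **process_kwargs,
) -> tuple[list[ProcessedTweet], CountsTable]:
    """Apply the three filtering stages in order and count retained tweets.

    A tweet is retained iff it matches the context rule, carries at least one
    topic, and its country code is in ``countries``.  Retained tweets carry
    their topic set; the counts table counts a tweet once per matched topic,
    so row totals may exceed distinct-tweet counts.
    """
    country_set = set(countries)
    topic_names = [r.name for r in topics]
    cells: dict[tuple[str, str], int] = {
        (c, t): 0 for c in sorted(country_set) for t in topic_names
    }
    retained: list[ProcessedTweet] = []
    for raw in raws:
        tweet = process(raw, stopwords=stopwords, **process_kwargs)
        toks = tweet.lemmas if use_lemmas else tweet.tokens
        if not matches(context, toks):
            continue
        matched = classify_topics(tweet, topics, use_lemmas=use_lemmas)
        if not matched:
            continue
        if tweet.country_code not in country_set:
            continue
        tweet.topics = matched
        retained.append(tweet)
        for t in matched:
            cells[(tweet.country_code, t)] += 1
    return retained, report_counts(cells)


def load_rules(
    path: str | Path,
) -> tuple[RuleSet, list[RuleSet], set[str]]:
    """Read a rules config file with ``context``, ``topics`` and ``countries``
    sections; returns (context rule, topic rules, country codes)."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    for key in ("context", "topics", "countries"):
        if key not in data:
            raise ValueError(f"{path}: missing {key!r} section")
    context = RuleSet.from_phrases("context", data["context"])
    topic_rules = [
        RuleSet.from_phrases(name, phrases) for name, phrases in data["topics"].items()
    ]
    countries = {str(c).upper() for c in data["countries"]}
    return context, topic_rules, countries


def default_rules_path() -> Path:
    return Path(__file__).parent / "data" / "rules_default.yaml"
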