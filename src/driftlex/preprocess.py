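"""Tweet cleaning and linguistic processing.

Cleaning removes URLs, @-mentions, #-hashtags, emoji/smileys and non-letter
special characters (in that order); tokenization keeps letter runs only;
the default lemmatizer is a download-free Spanish plural suffix stripper
behind an injectable interface.
"""

from __future__ import annotations

import datetime
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

from .lexicon import normalize_term

logger = logging.getLogger(__name__)

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_MENTION_RE = re.compile(r"@\w+")
_HASHTAG_RE = re.compile(r"#\w+")
# Emoji / pictograph / symbol blocks plus variation selectors.
_EMOJI_RE = re.compile(
    "["
    "\U0001f000-\U0001faff"
    "\U00002600-\U000027bf"
    "\U0001f1e6-\U0001f1ff"
    "\U00002190-\U000021ff"
    "\U00002b00-\U00002bff"
    "\ufe00-\ufe0f"
    "\u200d"
    "]+"
)
# Anything that is not a word character or whitespace, plus underscore.
_SPECIAL_RE = re.compile(r"[^\w\s]|_")
_WS_RE = re.compile(r"\s+")


def _letter_runs(text: str) -> list[str]:
    # str.isalpha, not \w: regex word chars admit non-letter numerics like "¼"
    runs: list[str] = []
    cur: list[str] = []
    for c in text:
        if c.isalpha():
            cur.append(c)
        elif cur:
            runs.append("".join(cur))
            cur = []
    if cur:
        runs.append("".join(cur))
    return runs


def clean_text(text: str, keep_hashtag_word: bool = False) -> str:
    """Strip non-linguistic content from a tweet.

    Removal order: URLs, @-mentions, #-hashtag tokens (the whole token, unless
    ``keep_hashtag_word``), emoji/smiley codepoints, remaining non-letter
    special characters.  Whitespace runs collapse to single spaces; the result
    is trimmed.  Never lengthens its input.
    """
    s = _URL_RE.sub(" ", text)
    s = _MENTION_RE.sub(" ", s)
    if keep_hashtag_word:
        s = s.replace("#", " ")
    else:
        s = _HASHTAG_RE.sub(" ", s)
    s = _EMOJI_RE.sub(" ", s)
    s = _SPECIAL_RE.sub(" ", s)
    return _WS_RE.sub(" ", s).strip()


def tokenize(text: str) -> list[str]:
    """Split cleaned text into normalized letter-only tokens.

    Splits on any non-letter character, normalizes each token via
    :func:`normalize_term`, and drops tokens shorter than 2 letters.
    """
    tokens = [normalize_term(t) for t in _letter_runs(text)]
    return [t for t in tokens if len(t) >= 2 and t.isalpha()]


#: Plural-looking words that are not plurals (or whose stem would mangle).
LEMMATIZER_EXCEPTIONS: frozenset[str] = frozenset(
    {
        "mes",
        "tres",
        "dos",
        "seis",
        "pais",
        "gas",
        "gracias",
        "crisis",
        "virus",
        "lunes",
        "martes",
        "jueves",
        "viernes",
        "despues",
        "entonces",
        "menos",
        "mas",
    }
)

Lemmatizer = Callable[[str], str]


def default_lemmatizer(token: str) -> str:
    """Rule-table lemmatizer: strip plural "-es"/"-s" when the stem keeps
    at least 3 letters; exception list guards common false plurals."""
    if token in LEMMATIZER_EXCEPTIONS:
        return token
    if token.endswith("es") and len(token) - 2 >= 3:
        return token[:-2]
    if token.endswith("s") and len(token) - 1 >= 3:
        return token[:-1]
    return token


def lemmatize(tokens: list[str], lemmatizer: Lemmatizer | None = None) -> list[str]:
    """Map each token through the active lemmatizer (injectable)."""
    lemmatizer = lemmatizer or default_lemmatizer
    return [lemmatizer(t) for t in tokens]


def remove_stopwords(lemmas: list[str], stopwords: frozenset[str] | set[str]) -> list[str]:
    """Order-preserving removal of stopword lemmas."""
    return [x for x in lemmas if x not in stopwords]


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a one-term-per-line stopword file; terms are normalized."""
    out = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        term = normalize_term(line)
        if term:
            out.add(term)
    return frozenset(out)


def default_stopwords() -> frozenset[str]:
    """The bundled Spanish stopword list."""
    return load_stopwords(Path(__file__).parent / "data" / "stopwords_es.txt")


@dataclass
class RawTweet:
    """A stream record prior to any processing."""

    id: str
    created_at: datetime.datetime
    text: str
    country_code: str | None = None

    @property
    def day(self) -> datetime.date:
        """UTC calendar date of creation."""
        dt = self.created_at
        if dt.tzinfo is not None:
            dt = dt.astimezone(datetime.timezone.utc)
        return dt.date()


@dataclass
class ProcessedTweet:
    """A tweet after cleaning, tokenization, lemmatization and stopword
    removal; ``topics`` is filled by the filtering stage."""

    id: str
    day: datetime.date
    country_code: str | None
    clean_text: str
    tokens: list[str]
    lemmas: list[str]
    topics: set[str] = field(default_factory=set)


# Part-of-speech tags considered content words when a tagger is injected.
_CONTENT_TAGS = {"NOUN", "VERB", "ADJ", "ADV"}

PosTagger = Callable[[list[str]], list[str]]


def process(
    raw: RawTweet,
    stopwords: frozenset[str] | set[str] = frozenset(),
    lemmatizer: Lemmatizer | None = None,
    tagger: PosTagger | None = None,
    keep_hashtag_word: bool = False,
) -> ProcessedTweet:
    """Run the full cleaning chain on one tweet.

    Composition: clean_text -> tokenize -> (optional PoS content-word filter)
    -> lemmatize -> remove_stopwords.  Deterministic given identical inputs.
    """
    cleaned = clean_text(raw.text, keep_hashtag_word=keep_hashtag_word)
    tokens = tokenize(cleaned)
    kept = tokens
    if tagger is not None:
        tags = tagger(tokens)
        kept = [t for t, tag in zip(tokens, tags) if tag in _CONTENT_TAGS]
    lemmas = remove_stopwords(lemmatize(kept, lemmatizer), stopwords)
    return ProcessedTweet(
        id=raw.id,
        day=raw.day,
        country_code=raw.country_code,
        clean_text=cleaned,
        tokens=tokens,
        lemmas=lemmas,
    )


def read_jsonl(path: str | Path, skipped: list[int] | None = None) -> Iterator[RawTweet]:
    """Yield :class:`RawTweet` from a JSON-lines file.

    Expected keys per object: ``id``, ``created_at`` (ISO-8601), ``text``,
    ``country_code`` (nullable).  Records with unparseable timestamps or
    missing keys are skipped and logged; ``skipped``, when given, receives one
    element per skipped record (its line number).
    """
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                created = datetime.datetime.fromisoformat(
                    str(obj["created_at"]).replace("Z", "+00:00")
                )
                yield RawTweet(
                    id=str(obj["id"]),
                    created_at=created,
                    text=str(obj["text"]),
                    country_code=obj.get("country_code"),
                )
            except (KeyError, ValueError, TypeError) as exc:
                logger.warning("%s:%d: skipping bad record (%s)", path, lineno, exc)
                if skipped is not None:
                    skipped.append(lineno)


def write_jsonl(tweets: Iterable[RawTweet], path: str | Path) -> int:
    """Write tweets as JSON-lines; returns the record count."""
    n = 0
    with Path(path).open("w", encoding="utf-8") as fh:
        for t in tweets:
            fh.write(
                json.dumps(
                    {
                        "id": t.id,
                        "created_at": t.created_at.isoformat(),
                        "text": t.text,
                        "country_code": t.country_code,
                    },
                    ensure_ascii=False,
                    sort_keys=True,
                )
                + "\n"
            )
            n += 1
    return n


def process_stream(
    raws: Iterable[RawTweet],
    stopwords: frozenset[str] | set[str] = frozenset(),
    dedupe: bool = False,
    **kwargs,
) -> Iterator[ProcessedTweet]:
    """Process a stream in order; with ``dedupe``, drop exact duplicate texts
    within the same day."""
    seen: set[tuple[datetime.date, str]] = set()
    for raw in raws:
        if dedupe:
            key = (raw.day, raw.text)
            if key in seen:
                continue
            seen.add(key)
        yield process(raw, stopwords=stopwords, **kwargs)
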