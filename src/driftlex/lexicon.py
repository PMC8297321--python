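"""Polarity lexicon: term normalization, seed loading, and the mutable store.

The lexicon maps normalized lemmas to sentiment polarities in [-1, 1].
Entries are either *seed* (loaded from a two-column TSV, e.g. a SenticNet-style
export) or *learned* (inserted by the engine while processing a stream).
"""

from __future__ import annotations

import datetime
import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

logger = logging.getLogger(__name__)

#: Private-use codepoint used to shield "ñ" from diacritic folding.
_ENYE_SHIELD = "\ue000"


def normalize_term(text: str) -> str:
    """Normalize a term for matching: lowercase, fold diacritics, strip.

    Accented vowels and "ü" are folded to their base letters so that
    unaccented user spellings still match ("antígenos" -> "antigenos").
    "ñ" is preserved: folding it to "n" would merge distinct Spanish
    words (e.g. "año" / "ano").  The function is idempotent.
    """
    s = unicodedata.normalize("NFC", text).lower().strip()
    s = s.replace("ñ", _ENYE_SHIELD)
    s = unicodedata.normalize("NFD", s)
    s = "".join(c for c in s if not unicodedata.combining(c))
    return s.replace(_ENYE_SHIELD, "ñ")


@dataclass
class LexiconEntry:
    """One word in the lexicon.

    Attributes
    ----------
    lemma : str
        Normalized lowercase lemma; must equal ``normalize_term(lemma)``.
    polarity : float
        Sentiment polarity in [-1, 1].
    origin : str
        ``"seed"`` or ``"learned"``.
    created_on : datetime.date or None
        Day the entry was learned; ``None`` for seed entries.
    total_frequency : int
        Cumulative number of scored tweets the lemma appeared in.
    """

    lemma: str
    polarity: float
    origin: str = "seed"
    created_on: datetime.date | None = None
    total_frequency: int = 0

    def __post_init__(self) -> None:
        if not self.lemma:
            raise ValueError("lemma must be non-empty")
        if self.lemma != normalize_term(self.lemma):
            raise ValueError(f"lemma {self.lemma!r} is not normalized")
        if not -1.0 <= self.polarity <= 1.0:
            raise ValueError(f"polarity {self.polarity} outside [-1, 1]")
        if self.origin not in ("seed", "learned"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.origin == "learned" and self.created_on is None:
            raise ValueError("learned entries require created_on")
        if self.total_frequency < 0:
            raise ValueError("total_frequency must be non-negative")


@dataclass
class Lexicon:
    """Mutable map lemma -> :class:`LexiconEntry`."""

    entries: dict[str, LexiconEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, lemma: str) -> bool:
        return lemma in self.entries

    def __getitem__(self, lemma: str) -> LexiconEntry:
        return self.entries[lemma]

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def add(self, entry: LexiconEntry) -> None:
        if entry.lemma in self.entries:
            raise KeyError(f"duplicate lemma {entry.lemma!r}")
        self.entries[entry.lemma] = entry

    def polarity(self, lemma: str) -> float:
        return self.entries[lemma].polarity

    def set_polarity(self, lemma: str, value: float) -> None:
        if not -1.0 <= value <= 1.0:
            raise ValueError(f"polarity {value} outside [-1, 1]")
        self.entries[lemma].polarity = value

    def copy(self) -> "Lexicon":
        return Lexicon(
            {
                k: LexiconEntry(
                    v.lemma, v.polarity, v.origin, v.created_on, v.total_frequency
                )
                for k, v in self.entries.items()
            }
        )


class LexiconFormatError(ValueError):
    """Raised for malformed lexicon files; message names the line number."""


def load_seed_lexicon(path: str | Path) -> Lexicon:
    """Load a seed lexicon from a TSV file of ``lemma<TAB>polarity`` rows.

    A header line ``lemma\\tpolarity`` is skipped if present.  Rows may carry
    two extra columns (origin, created_on) as written by :func:`save_lexicon`.
    Duplicate lemmas after normalization keep the first occurrence and log a
    warning.  Out-of-range polarities and malformed rows raise
    :class:`LexiconFormatError` naming the offending line.
    """
    path = Path(path)
    lex = Lexicon()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if lineno == 1 and line.split("\t")[:2] == ["lemma", "polarity"]:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise LexiconFormatError(
                    f"{path}:{lineno}: expected at least 2 tab-separated fields"
                )
            lemma = normalize_term(fields[0])
            if not lemma:
                raise LexiconFormatError(f"{path}:{lineno}: empty lemma")
            try:
                polarity = float(fields[1])
            except ValueError as exc:
                raise LexiconFormatError(
                    f"{path}:{lineno}: polarity {fields[1]!r} is not a number"
                ) from exc
            if not -1.0 <= polarity <= 1.0:
                raise LexiconFormatError(
                    f"{path}:{lineno}: polarity {polarity} outside [-1, 1]"
                )
            origin = "seed"
            created_on: datetime.date | None = None
            if len(fields) >= 4 and fields[2]:
                origin = fields[2]
                try:
                    created_on = datetime.date.fromisoformat(fields[3])
                except ValueError as exc:
                    raise LexiconFormatError(
                        f"{path}:{lineno}: bad created_on date {fields[3]!r}"
                    ) from exc
            if lemma in lex:
                logger.warning(
                    "%s:%d: duplicate lemma %r after normalization; keeping first",
                    path,
                    lineno,
                    lemma,
                )
                continue
            lex.add(LexiconEntry(lemma, polarity, origin, created_on))
    return lex


def save_lexicon(lex: Lexicon, path: str | Path) -> None:
    """Write a lexicon as TSV; round-trips through :func:`load_seed_lexicon`.

    Polarities are written with 6 decimal places.  Learned entries carry two
    extra columns (origin, created_on).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("lemma\tpolarity\n")
        for lemma in sorted(lex.entries):
            e = lex.entries[lemma]
            if e.origin == "learned":
                fh.write(
                    f"{e.lemma}\t{e.polarity:.6f}\t{e.origin}\t{e.created_on.isoformat()}\n"
                )
            else:
                fh.write(f"{e.lemma}\t{e.polarity:.6f}\n")
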