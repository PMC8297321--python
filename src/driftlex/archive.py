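"""Append-only archive of per-word daily sentiment history."""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class SentimentRecord:
    """One word's state after a daily update.

    ``daily_mean`` is the mean score of the day's tweets containing the word,
    ``daily_count`` the number of such tweets, ``polarity_after`` the updated
    lexicon polarity.  ``country`` identifies the engine partition ("all" for
    pooled runs).
    """

    lemma: str
    day: datetime.date
    polarity_after: float
    daily_mean: float
    daily_count: int
    country: str = "all"

    def __post_init__(self) -> None:
        if not -1.0 <= self.polarity_after <= 1.0:
            raise ValueError(f"polarity_after {self.polarity_after} outside [-1, 1]")
        if not -1.0 <= self.daily_mean <= 1.0:
            raise ValueError(f"daily_mean {self.daily_mean} outside [-1, 1]")
        if self.daily_count < 1:
            raise ValueError("daily_count must be >= 1")


class Archive:
    """Record store indexed by (country, lemma, day); one record per key."""

    def __init__(self) -> None:
        self.records: list[SentimentRecord] = []
        self._index: dict[tuple[str, str, datetime.date], SentimentRecord] = {}

    def __len__(self) -> int:
        return len(self.records)

    def append(self, rec: SentimentRecord) -> None:
        key = (rec.country, rec.lemma, rec.day)
        if key in self._index:
            raise KeyError(f"duplicate archive record for {key}")
        self._index[key] = rec
        self.records.append(rec)

    def get(self, country: str, lemma: str, day: datetime.date) -> SentimentRecord | None:
        return self._index.get((country, lemma, day))

    def get_series(
        self,
        lemma: str,
        country: str = "all",
        start: datetime.date | None = None,
        end: datetime.date | None = None,
    ) -> list[tuple[datetime.date, float]]:
        """Chronologically sorted (day, polarity_after) pairs; bounds inclusive."""
        out = [
            (r.day, r.polarity_after)
            for r in self.records
            if r.lemma == lemma
            and r.country == country
            and (start is None or r.day >= start)
            and (end is None or r.day <= end)
        ]
        out.sort(key=lambda p: p[0])
        return out

    def lemmas(self, country: str = "all") -> list[str]:
        return sorted({r.lemma for r in self.records if r.country == country})


_CSV_HEADER = "country,lemma,day,polarity_after,daily_mean,daily_count"


def export_csv(archive: Archive, path: str | Path) -> None:
    """Write the archive as CSV; polarities with 6 decimal places."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_CSV_HEADER + "\n")
        for r in archive.records:
            fh.write(
                f"{r.country},{r.lemma},{r.day.isoformat()},"
                f"{r.polarity_after:.6f},{r.daily_mean:.6f},{r.daily_count}\n"
            )


class ArchiveFormatError(ValueError):
    """Raised for malformed archive files; message names the line number."""


def import_csv(path: str | Path) -> Archive:
    """Read an archive CSV written by :func:`export_csv` (round-trip)."""
    archive = Archive()
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != _CSV_HEADER:
            raise ArchiveFormatError(f"{path}:1: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != 6:
                raise ArchiveFormatError(f"{path}:{lineno}: expected 6 fields")
            try:
                rec = SentimentRecord(
                    country=fields[0],
                    lemma=fields[1],
                    day=datetime.date.fromisoformat(fields[2]),
                    polarity_after=float(fields[3]),
                    daily_mean=float(fields[4]),
                    daily_count=int(fields[5]),
                )
            except ValueError as exc:
                raise ArchiveFormatError(f"{path}:{lineno}: {exc}") from exc
            archive.append(rec)
    return archive
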