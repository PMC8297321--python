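"""Synthetic tweet-stream generator with planted word-sentiment
trajectories, plus recovery metrics.

Each trajectory tweet embeds a context keyword, a topic keyword, the
trajectory word, four filler lemmas from the fixture lexicon, and one
*adjuster* lemma chosen from the lexicon's polarity grid so the tweet's
matched-lemma mean lands on the planted value mu_w(d) plus Gaussian noise
(up to grid resolution).  Background tweets carry fillers only and no
context keyword, so they are dropped by the filter.  Recovery metrics then
compare planted trajectories against the engine's archived polarity series.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .archive import Archive
from .lexicon import Lexicon, LexiconEntry
from .preprocess import RawTweet

logger = logging.getLogger(__name__)

_SHAPES = ("constant", "linear", "step")


@dataclass(frozen=True)
class TrajectorySpec:
    """A planted per-word mean-sentiment trajectory."""

    lemma: str
    shape: str
    start_value: float
    end_value: float | None = None
    step_day: int | None = None
    tweets_per_day: int = 50
    topic: str | None = None

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape != "constant" and self.end_value is None:
            raise ValueError(f"{self.shape} trajectory needs end_value")
        if self.shape == "step" and self.step_day is None:
            raise ValueError("step trajectory needs step_day")
        if self.tweets_per_day < 1:
            raise ValueError("tweets_per_day must be positive")
        for v in (self.start_value, self.end_value):
            if v is not None and not -1.0 <= v <= 1.0:
                raise ValueError(f"trajectory value {v} outside [-1, 1]")

    def mu(self, day_index: int, n_days: int) -> float:
        """Planted mean on day ``day_index`` (0-based) of ``n_days``."""
        if self.shape == "constant":
            return self.start_value
        if self.shape == "linear":
            frac = day_index / (n_days - 1) if n_days > 1 else 0.0
            return self.start_value + (self.end_value - self.start_value) * frac
        return self.start_value if day_index < self.step_day else self.end_value


@dataclass
class SynthConfig:
    """Full scenario description; a fixed seed makes output reproducible."""

    seed: int = 0
    n_days: int = 30
    countries: list[str] = field(default_factory=lambda: ["ES"])
    topic_vocab: dict[str, list[str]] = field(
        default_factory=lambda: {"vaccines": ["pfizer"], "government": ["democracia"]}
    )
    context_keywords: list[str] = field(default_factory=lambda: ["covid"])
    filler_lexicon_size: int = 41
    noise_sd: float = 0.05
    trajectories: list[TrajectorySpec] = field(default_factory=list)
    background_tweets_per_day: int = 20
    start_date: datetime.date = datetime.date(2020, 3, 1)


# Lemma alphabet excludes "s" so generated lemmas are fixed points of the
# default plural-stripping lemmatizer.
_NAME_ALPHABET = "abcdefghijklmnopqrtuvwxyz"


def _alpha_name(i: int) -> str:
    base = len(_NAME_ALPHABET)
    letters = []
    for _ in range(5):
        letters.append(_NAME_ALPHABET[i % base])
        i //= base
    return "".join(reversed(letters))


def generate_fixture_lexicon(n: int, seed: int = 0) -> Lexicon:
    """Fixture lexicon of ``n`` lemmas with polarities on the uniform grid
    over [-1, 1] (resolution 2/(n-1)); n >= 21 so adjuster selection can
    approximate any target mean."""
    if n < 21:
        raise ValueError("fixture lexicon needs n >= 21 (grid too coarse below)")
    lex = Lexicon()
    grid = np.linspace(-1.0, 1.0, n)
    for i, p in enumerate(grid):
        lex.add(LexiconEntry(lemma=f"f{_alpha_name(i)}", polarity=float(p)))
    return lex


_N_FILLERS = 4
_FILLER_WINDOW = 0.35
_MAX_RESAMPLE = 100


class _GridAllocator:
    """Nearest-unused-index allocator over the polarity grid.

    Single-use allocation matters: a filler lemma reused across days has its
    polarity rewritten by the engine, which feeds engine output back into
    tweet scores and lets the whole system drift to a consensus value
    instead of the planted trajectory.  Uses two path-compressed "next free"
    pointer arrays, so allocation is near O(1) amortized.
    """

    def __init__(self, n: int):
        self.n = n
        # _right[i]: candidate for smallest free index >= i (n = none).
        # _left[i]: candidate for largest free index <= i (-1 = none).
        self._right = list(range(n + 1))
        self._left = list(range(n))

    def _find_right(self, i: int) -> int:
        root = i
        while root < self.n and self._right[root] != root:
            root = self._right[root]
        while i < self.n and self._right[i] != root:
            self._right[i], i = root, self._right[i]
        return root

    def _find_left(self, i: int) -> int:
        root = i
        while root >= 0 and self._left[root] != root:
            root = self._left[root]
        while i >= 0 and self._left[i] != root:
            self._left[i], i = root, self._left[i]
        return root

    def take_nearest(self, i: int) -> int | None:
        """Claim and return the unused index nearest to ``i`` (ties go low)."""
        i = min(max(i, 0), self.n - 1)
        r = self._find_right(i)
        l = self._find_left(i)
        if r >= self.n and l < 0:
            return None
        if l < 0 or (r < self.n and (r - i) < (i - l)):
            idx = r
        else:
            idx = l
        self._right[idx] = idx + 1
        self._left[idx] = idx - 1
        return idx


def _make_trajectory_tokens(
    rng: np.random.Generator,
    target: float,
    lemmas: list[str],
    pols: np.ndarray,
    alloc: _GridAllocator | None,
) -> tuple[list[str], int]:
    """Fillers + adjuster whose mean polarity hits ``target`` exactly up to
    grid resolution.  Fillers come from the grid window around the target;
    the adjuster polarity is (k+1)*target - k*filler_mean, clipped to [-1, 1]
    when unreachable.  With an allocator, every lemma is claimed at most
    once per stream (see :class:`_GridAllocator`); without one, sampling
    retries until the adjuster is representable.  Returns the token list and
    1 if clipping occurred."""
    n = len(pols)
    step = 2.0 / (n - 1)

    def grid_index(value: float) -> int:
        return int(round((value + 1.0) / step))

    if alloc is not None:
        idx = []
        for _ in range(_N_FILLERS):
            want = grid_index(target + rng.uniform(-_FILLER_WINDOW, _FILLER_WINDOW))
            got = alloc.take_nearest(want)
            if got is None:
                raise RuntimeError("fixture lexicon exhausted; increase filler_lexicon_size")
            idx.append(got)
        needed = (_N_FILLERS + 1) * target - _N_FILLERS * float(pols[idx].mean())
        clipped = int(not -1.0 <= needed <= 1.0)
        needed = min(1.0, max(-1.0, needed))
        adjuster = alloc.take_nearest(grid_index(needed))
        if adjuster is None:
            raise RuntimeError("fixture lexicon exhausted; increase filler_lexicon_size")
        return [lemmas[i] for i in idx + [adjuster]], clipped

    window = np.flatnonzero(np.abs(pols - target) <= _FILLER_WINDOW)
    if window.size < _N_FILLERS:
        center = int(np.argmin(np.abs(pols - target)))
        lo = max(0, center - _N_FILLERS)
        window = np.arange(lo, min(n, lo + 2 * _N_FILLERS + 1))
    clipped = 1
    for _ in range(_MAX_RESAMPLE):
        idx = rng.choice(window, size=_N_FILLERS, replace=True)
        needed = (_N_FILLERS + 1) * target - _N_FILLERS * float(pols[idx].mean())
        if -1.0 <= needed <= 1.0:
            clipped = 0
            break
    needed = min(1.0, max(-1.0, needed))
    adjuster = int(np.argmin(np.abs(pols - needed)))
    return [lemmas[i] for i in list(idx) + [adjuster]], clipped


def generate_stream(
    cfg: SynthConfig, lex: Lexicon
) -> tuple[list[RawTweet], pd.DataFrame]:
    """Generate the multi-day multi-country stream and its ground truth.

    Returns the tweet list (trajectory tweets then background tweets, per
    day) and a table with one row per (lemma, day) holding the planted mean
    ``mu``.  Background tweets never contain context keywords.
    """
    rng = np.random.default_rng(cfg.seed)
    entries = sorted(lex.entries.values(), key=lambda e: (e.polarity, e.lemma))
    pols = np.array([e.polarity for e in entries])
    lemmas = [e.lemma for e in entries]
    # Single-use filler/adjuster allocation when the lexicon is big enough;
    # otherwise lemmas are reused (fine for small tests, but reuse feeds
    # engine updates back into scores on long runs).
    slots = (
        cfg.n_days
        * len(cfg.countries)
        * sum(t.tweets_per_day for t in cfg.trajectories)
        * (_N_FILLERS + 1)
    )
    alloc = _GridAllocator(len(entries)) if len(entries) >= 2 * slots else None
    if alloc is None and cfg.trajectories:
        logger.info(
            "lexicon size %d < 2x slot demand %d; sampling fillers with reuse",
            len(entries),
            slots,
        )
    topics = list(cfg.topic_vocab)
    tweets: list[RawTweet] = []
    truth_rows: list[dict] = []
    n_clipped = 0
    counter = 0
    for day_index in range(cfg.n_days):
        day = cfg.start_date + datetime.timedelta(days=day_index)
        for t_index, traj in enumerate(cfg.trajectories):
            topic = traj.topic or topics[t_index % len(topics)]
            topic_kw = cfg.topic_vocab[topic][0]
            mu = traj.mu(day_index, cfg.n_days)
            truth_rows.append({"lemma": traj.lemma, "day": day, "mu": mu})
            for country in cfg.countries:
                for j in range(traj.tweets_per_day):
                    eps = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
                    target = min(1.0, max(-1.0, mu + eps))
                    scored, clipped = _make_trajectory_tokens(
                        rng, target, lemmas, pols, alloc
                    )
                    n_clipped += clipped
                    words = [cfg.context_keywords[0], topic_kw, traj.lemma] + scored
                    rng.shuffle(words)
                    tweets.append(
                        RawTweet(
                            id=f"t{counter:08d}",
                            created_at=datetime.datetime(
                                day.year,
                                day.month,
                                day.day,
                                hour=12,
                                minute=j % 60,
                                second=counter % 60,
                                tzinfo=datetime.timezone.utc,
                            ),
                            text=" ".join(words),
                            country_code=country,
                        )
                    )
                    counter += 1
        for _ in range(cfg.background_tweets_per_day):
            fillers = [lemmas[i] for i in rng.integers(len(lemmas), size=5)]
            country = cfg.countries[int(rng.integers(len(cfg.countries)))]
            tweets.append(
                RawTweet(
                    id=f"t{counter:08d}",
                    created_at=datetime.datetime(
                        day.year,
                        day.month,
                        day.day,
                        hour=15,
                        second=counter % 60,
                        tzinfo=datetime.timezone.utc,
                    ),
                    text=" ".join(fillers),
                    country_code=country,
                )
            )
            counter += 1
    if n_clipped:
        logger.warning("%d tweets needed adjuster clipping (target unreachable)", n_clipped)
    truth = pd.DataFrame(truth_rows, columns=["lemma", "day", "mu"])
    return tweets, truth


@dataclass(frozen=True)
class RecoveryResult:
    """Planted-vs-recovered agreement for one trajectory word."""

    lemma: str
    pearson_r: float | None
    rmse: float | None
    n_days: int
    flag: str | None = None


def recovery_metrics(
    truth: pd.DataFrame,
    archive: Archive,
    country: str = "all",
) -> dict[str, RecoveryResult]:
    """Pearson r and RMSE between planted mu and archived polarity series.

    Metrics use days present in both series.  Fewer than 3 common days, or a
    zero-variance side (constant planted series), leaves the correlation
    undefined and flagged; RMSE is still reported when days suffice.
    """
    out: dict[str, RecoveryResult] = {}
    for lemma, group in truth.groupby("lemma"):
        planted = {row.day: row.mu for row in group.itertuples()}
        series = archive.get_series(lemma, country=country)
        common = [(planted[d], v) for d, v in series if d in planted]
        if len(common) < 3:
            out[lemma] = RecoveryResult(lemma, None, None, len(common), "too_few_days")
            continue
        mu = np.array([c[0] for c in common])
        rec = np.array([c[1] for c in common])
        rmse = float(np.sqrt(np.mean((mu - rec) ** 2)))
        if np.std(mu) == 0 or np.std(rec) == 0:
            out[lemma] = RecoveryResult(lemma, None, rmse, len(common), "zero_variance")
            continue
        r = float(np.corrcoef(mu, rec)[0, 1])
        out[lemma] = RecoveryResult(lemma, r, rmse, len(common), None)
    return out


def keyword_stopwords(cfg: SynthConfig) -> frozenset[str]:
    """Context and topic keywords as extra stopwords, so rule keywords never
    enter scoring or learning (mirrors treating pandemic-context words as
    domain stopwords)."""
    words = set(cfg.context_keywords)
    for phrases in cfg.topic_vocab.values():
        words.update(phrases)
    return frozenset(words)


def run_recovery(
    cfg: SynthConfig,
    alpha: float = 0.3,
    min_learn_occurrences: int = 2,
) -> dict[str, dict[str, RecoveryResult]]:
    """Generate the scenario, run the full pipeline, and measure recovery.

    Returns per-country recovery metrics keyed by country code.  The rule
    keywords are added to the stopword list (see :func:`keyword_stopwords`).
    """
    from . import filtering, preprocess
    from .engine import EngineConfig, run_stream

    lex = generate_fixture_lexicon(cfg.filler_lexicon_size, seed=cfg.seed)
    tweets, truth = generate_stream(cfg, lex)
    context = filtering.RuleSet.from_phrases("context", cfg.context_keywords)
    topic_rules = [
        filtering.RuleSet.from_phrases(name, phrases)
        for name, phrases in cfg.topic_vocab.items()
    ]
    stopwords = preprocess.default_stopwords() | keyword_stopwords(cfg)
    retained, _ = filtering.filter_stream(
        tweets, context, topic_rules, cfg.countries, stopwords=stopwords
    )
    engine_cfg = EngineConfig(alpha=alpha, min_learn_occurrences=min_learn_occurrences)
    out: dict[str, dict[str, RecoveryResult]] = {}
    for country in cfg.countries:
        archive, _ = run_stream(
            [t for t in retained if t.country_code == country],
            lex.copy(),
            engine_cfg,
            country=country,
        )
        out[country] = recovery_metrics(truth, archive, country=country)
    return out


def default_scenario(seed: int = 42) -> SynthConfig:
    """The reference recovery scenario: 60 days, one country, 200
    tweets/day/word, sigma = 0.05, with constant, linear and step planted
    shapes."""
    trajectories = [
        TrajectorySpec("trendflat", "constant", 0.5, tweets_per_day=200),
        TrajectorySpec("trendline", "linear", -0.6, 0.6, tweets_per_day=200),
        TrajectorySpec("trendstep", "step", -0.4, 0.4, step_day=30, tweets_per_day=200),
    ]
    n_days = 60
    countries = ["ES"]
    # 2x the filler/adjuster slot demand, so allocation stays single-use.
    slots = n_days * len(countries) * sum(t.tweets_per_day for t in trajectories) * (_N_FILLERS + 1)
    return SynthConfig(
        seed=seed,
        n_days=n_days,
        countries=countries,
        filler_lexicon_size=2 * slots + 1,
        noise_sd=0.05,
        background_tweets_per_day=50,
        trajectories=trajectories,
    )
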