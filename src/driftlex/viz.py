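"""Visualisation layer: co-occurrence statistics, PPMI/cosine similarity,
deterministic classical-MDS word-cloud layout, frequency clouds, and the
fixed polarity->colour / frequency->size rendering maps.

The word-cloud semantics are: 2-D distance encodes relatedness (closer =
more related), colour encodes polarity (red negative, green positive), and
glyph size encodes frequency.  Snapshots taken on consecutive windows over
the same vocabulary support side-by-side comparison over time.
"""

from __future__ import annotations

import datetime
import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .archive import Archive
from .preprocess import ProcessedTweet

logger = logging.getLogger(__name__)


@dataclass
class CooccurrenceMatrix:
    """Symmetric tweet-level presence co-occurrence counts.

    ``counts[i][j]`` is the number of tweets containing both ``vocabulary[i]``
    and ``vocabulary[j]``; the diagonal holds per-word tweet frequencies.
    """

    vocabulary: list[str]
    counts: np.ndarray
    doc_count: int


def cooccurrence(tweets: Sequence[ProcessedTweet], vocab: Sequence[str]) -> CooccurrenceMatrix:
    """Count tweet-level joint presence for every vocabulary pair."""
    if not vocab:
        raise ValueError("vocab must be non-empty")
    vocab = list(vocab)
    index = {w: i for i, w in enumerate(vocab)}
    counts = np.zeros((len(vocab), len(vocab)), dtype=np.int64)
    for t in tweets:
        present = sorted({index[x] for x in t.lemmas if x in index})
        for a in range(len(present)):
            for b in range(a, len(present)):
                i, j = present[a], present[b]
                counts[i, j] += 1
                if i != j:
                    counts[j, i] += 1
    return CooccurrenceMatrix(vocabulary=vocab, counts=counts, doc_count=len(tweets))


def similarity(M: CooccurrenceMatrix) -> np.ndarray:
    """Cosine similarity between rows of the PPMI weighting of the counts.

    PPMI(i, j) = max(0, log(n * c_ij / (c_ii * c_jj))) with n the tweet
    count.  A word whose PPMI row vanishes despite having occurrences (e.g.
    perfect co-occurrence in every tweet leaves zero pointwise information)
    falls back to its raw count row so such words still compare by profile.
    Words with any occurrence have self-similarity 1; words with zero
    occurrences are 0 against everything (themselves included).
    """
    C = np.asarray(M.counts, dtype=float)
    n = float(max(M.doc_count, 1))
    diag = np.diag(C).copy()
    V = len(M.vocabulary)
    ppmi = np.zeros_like(C)
    nz = diag > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (C * n) / np.outer(diag, diag)
    mask = (C > 0) & np.outer(nz, nz)
    ppmi[mask] = np.maximum(0.0, np.log(ratio[mask]))
    degenerate = (np.linalg.norm(ppmi, axis=1) == 0) & nz
    ppmi[degenerate] = C[degenerate]
    norms = np.linalg.norm(ppmi, axis=1)
    S = np.zeros((V, V))
    ok = norms > 0
    if ok.any():
        normed = ppmi[ok] / norms[ok, None]
        S[np.ix_(ok, ok)] = normed @ normed.T
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, np.where(nz, 1.0, 0.0))
    return S


def layout(S: np.ndarray, seed: int = 0) -> np.ndarray:
    """Deterministic 2-D embedding of a similarity matrix by classical MDS.

    Distances are D = 1 - S.  The double-centered Gram matrix is
    eigendecomposed and the two leading non-negative eigendimensions kept;
    coordinates are centered at the origin.  Each axis sign is fixed so its
    largest-magnitude coordinate is positive.  Rank-deficient inputs get
    zero-padded coordinates.  ``seed`` is accepted for interface stability;
    the procedure has no randomness.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    V = S.shape[0]
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    J = np.eye(V) - np.full((V, V), 1.0 / V)
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    X = np.zeros((V, 2))
    for k in range(2):
        if k >= V:
            break
        lam = eigvals[order[k]]
        if lam <= 1e-12:
            continue
        axis = eigvecs[:, order[k]] * np.sqrt(lam)
        if axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
        X[:, k] = axis
    X -= X.mean(axis=0, keepdims=True)
    return X


@dataclass
class CloudSnapshot:
    """Per-word (x, y, polarity, frequency) layout for a date window."""

    window: tuple[datetime.date, datetime.date]
    words: list[tuple[str, float, float, float, int]]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "window": [self.window[0].isoformat(), self.window[1].isoformat()],
            "words": [
                {
                    "lemma": w,
                    "x": round(x, 6),
                    "y": round(y, 6),
                    "polarity": round(p, 6),
                    "frequency": f,
                }
                for (w, x, y, p, f) in self.words
            ],
        }
        text = json.dumps(payload, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def snapshot(
    archive: Archive,
    tweets: Sequence[ProcessedTweet],
    words: Sequence[str],
    window: tuple[datetime.date, datetime.date],
    country: str = "all",
) -> CloudSnapshot:
    """Build a word-cloud snapshot for a date window.

    Polarity is the last archived value within the window and frequency the
    summed daily counts; coordinates come from co-occurrence -> similarity ->
    layout over the window's tweets.  Words without archive records in the
    window are excluded with a warning; fewer than 2 plottable words is an
    error.
    """
    start, end = window
    kept: list[str] = []
    polarity: dict[str, float] = {}
    frequency: dict[str, int] = {}
    for w in words:
        series = archive.get_series(w, country=country, start=start, end=end)
        if not series:
            logger.warning("word %r has no archive records in %s..%s; excluded", w, start, end)
            continue
        kept.append(w)
        polarity[w] = series[-1][1]
        frequency[w] = sum(
            r.daily_count
            for r in archive.records
            if r.lemma == w and r.country == country and start <= r.day <= end
        )
    if len(kept) < 2:
        raise ValueError(f"need at least 2 plottable words, got {len(kept)}")
    window_tweets = [t for t in tweets if start <= t.day <= end]
    M = cooccurrence(window_tweets, kept)
    X = layout(similarity(M))
    return CloudSnapshot(
        window=window,
        words=[
            (w, float(X[i, 0]), float(X[i, 1]), polarity[w], frequency[w])
            for i, w in enumerate(kept)
        ],
    )


def frequency_cloud(
    tweets: Sequence[ProcessedTweet],
    stopwords: frozenset[str] | set[str] = frozenset(),
) -> list[tuple[str, int]]:
    """Descending (lemma, frequency) tally after extra stopword removal.

    Ties break alphabetically for determinism.
    """
    tally = Counter()
    for t in tweets:
        for x in t.lemmas:
            if x not in stopwords:
                tally[x] += 1
    return sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))


def polarity_to_color(p: float) -> tuple[float, float, float]:
    """Fixed monotone polarity -> RGB map: red at -1, grey at 0, green at +1."""
    p = min(1.0, max(-1.0, p))
    neutral = (0.65, 0.65, 0.65)
    if p < 0:
        t = -p
        lo = (0.85, 0.10, 0.10)
    else:
        t = p
        lo = (0.05, 0.60, 0.05)
    return tuple((1 - t) * n + t * c for n, c in zip(neutral, lo))


def frequency_to_size(freq: int, base: float = 8.0, scale: float = 6.0) -> float:
    """Fixed monotone frequency -> font size map, affine in log(1+frequency)."""
    if freq < 0:
        raise ValueError("frequency must be non-negative")
    return base + scale * float(np.log1p(freq))


def render_snapshot(snap: CloudSnapshot, path: str | Path, title: str = "") -> None:
    """Render a snapshot as a 2-D annotated scatter image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    for (w, x, y, p, f) in snap.words:
        ax.text(
            x,
            y,
            w,
            color=polarity_to_color(p),
            fontsize=frequency_to_size(f),
            ha="center",
            va="center",
        )
    xs = [w[1] for w in snap.words]
    ys = [w[2] for w in snap.words]
    pad_x = (max(xs) - min(xs) or 1.0) * 0.25
    pad_y = (max(ys) - min(ys) or 1.0) * 0.25
    ax.set_xlim(min(xs) - pad_x, max(xs) + pad_x)
    ax.set_ylim(min(ys) - pad_y, max(ys) + pad_y)
    ax.set_title(title or f"{snap.window[0]} .. {snap.window[1]}")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_frequency_cloud(
    items: Sequence[tuple[str, int]],
    path: str | Path,
    max_words: int = 40,
    seed: int = 0,
) -> None:
    """Render a simple frequency word cloud (size = frequency) on a grid
    jittered deterministically by ``seed``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rng = np.random.default_rng(seed)
    items = list(items)[:max_words]
    fig, ax = plt.subplots(figsize=(7, 5))
    cols = int(np.ceil(np.sqrt(len(items)))) or 1
    for k, (w, f) in enumerate(items):
        x = (k % cols) + rng.uniform(-0.2, 0.2)
        y = (k // cols) + rng.uniform(-0.2, 0.2)
        ax.text(x, y, w, fontsize=frequency_to_size(f), ha="center", va="center")
    ax.set_xlim(-1, cols)
    ax.set_ylim(-1, int(np.ceil(len(items) / cols)))
    ax.axis("off")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_trends(
    series: dict[str, list[tuple[datetime.date, float]]],
    path: str | Path,
    title: str = "",
) -> None:
    """Line plot of per-word polarity series over time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for label, pts in sorted(series.items()):
        if not pts:
            continue
        days, vals = zip(*pts)
        ax.plot(days, vals, label=label, linewidth=1.2)
    ax.set_ylim(-1.05, 1.05)
    ax.set_ylabel("polarity")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.autofmt_xdate()
    fig.savefig(path, dpi=120)
    plt.close(fig)
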