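import datetime
import itertools
import math

import numpy as np
import pytest

from driftlex.archive import Archive, SentimentRecord
from driftlex.viz import (
    CooccurrenceMatrix,
    cooccurrence,
    frequency_cloud,
    frequency_to_size,
    layout,
    polarity_to_color,
    similarity,
    snapshot,
)

from conftest import mk_tweet

D1 = datetime.date(2021, 3, 1)


def _tweets(lemma_lists):
    return [mk_tweet(f"t{i}", D1, ls) for i, ls in enumerate(lemma_lists)]


class TestCooccurrence:
    def test_perfect_cooccurrence(self):
        tweets = _tweets([["a", "b"]] * 5)
        M = cooccurrence(tweets, ["a", "b"])
        assert M.counts[0, 1] == 5
        assert M.counts[0, 0] == 5 and M.counts[1, 1] == 5

    def test_disjoint_words(self):
        tweets = _tweets([["a"], ["b"]])
        M = cooccurrence(tweets, ["a", "b"])
        assert M.counts[0, 1] == 0

    def test_presence_not_multiplicity(self):
        tweets = _tweets([["a", "a", "b"]])
        M = cooccurrence(tweets, ["a", "b"])
        assert M.counts[0, 0] == 1
        assert M.counts[0, 1] == 1

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        vocab = [f"w{i}" for i in range(6)]
        tweets = _tweets(
            [list(rng.choice(vocab, size=rng.integers(1, 5))) for _ in range(10)]
        )
        M = cooccurrence(tweets, vocab)
        # independent O(n * V^2) pair counting
        for i, j in itertools.product(range(6), repeat=2):
            expected = sum(
                1 for t in tweets if vocab[i] in t.lemmas and vocab[j] in t.lemmas
            )
            assert M.counts[i, j] == expected
        assert np.array_equal(M.counts, M.counts.T)
        # counts[i][j] <= min of diagonals
        diag = np.diag(M.counts)
        assert (M.counts <= np.minimum.outer(diag, diag)).all()

    def test_empty_vocab_rejected(self):
        with pytest.raises(ValueError):
            cooccurrence([], [])


class TestSimilarity:
    def test_identical_rows(self):
        tweets = _tweets([["a", "b"]] * 4)
        S = similarity(cooccurrence(tweets, ["a", "b"]))
        assert S[0, 1] == pytest.approx(1.0)

    def test_orthogonal_rows(self):
        tweets = _tweets([["a", "c"], ["b", "d"]] * 3)
        S = similarity(cooccurrence(tweets, ["a", "b", "c", "d"]))
        assert S[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_self_similarity_one_when_occurring(self):
        tweets = _tweets([["a"], ["a", "b"]])
        S = similarity(cooccurrence(tweets, ["a", "b", "zzz"]))
        assert S[0, 0] == pytest.approx(1.0)
        assert S[1, 1] == pytest.approx(1.0)
        # zero-occurrence word: similarity 0 everywhere
        assert S[2, 2] == 0.0
        assert S[2, 0] == 0.0

    def test_hand_computed_ppmi_cosine(self):
        # 3-word fixture, 4 tweets: ab, ab, ac, c
        tweets = _tweets([["a", "b"], ["a", "b"], ["a", "c"], ["c"]])
        M = cooccurrence(tweets, ["a", "b", "c"])
        S = similarity(M)
        # independent hand/NumPy oracle: ppmi = max(0, log(n*cij/(cii*cjj)))
        C = M.counts.astype(float)
        n = 4.0
        P = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                if C[i, j] > 0:
                    P[i, j] = max(0.0, math.log(n * C[i, j] / (C[i, i] * C[j, j])))
        for i, j in itertools.product(range(3), repeat=2):
            if i == j:
                assert S[i, j] == pytest.approx(1.0)
            else:
                num = float(P[i] @ P[j])
                den = float(np.linalg.norm(P[i]) * np.linalg.norm(P[j]))
                expected = num / den if den else 0.0
                assert S[i, j] == pytest.approx(min(1.0, expected), abs=1e-12)


class TestLayout:
    def test_two_identical_words_coincide(self):
        S = np.array([[1.0, 1.0], [1.0, 1.0]])
        X = layout(S)
        assert np.allclose(X[0], X[1], atol=1e-9)

    def test_related_pair_closer(self):
        S = np.array(
            [
                [1.0, 1.0, 0.0],
                [1.0, 1.0, 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        X = layout(S)
        d_ab = np.linalg.norm(X[0] - X[1])
        d_ac = np.linalg.norm(X[0] - X[2])
        assert d_ab < d_ac

    def test_centered_at_origin(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(0, 1, size=(5, 5))
        S = np.clip((A + A.T) / 2, 0, 1)
        np.fill_diagonal(S, 1.0)
        X = layout(S)
        assert np.allclose(X.mean(axis=0), 0.0, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(0, 1, size=(5, 5))
        S = np.clip((A + A.T) / 2, 0, 1)
        np.fill_diagonal(S, 1.0)
        perm = rng.permutation(5)
        X = layout(S)
        Xp = layout(S[np.ix_(perm, perm)])
        # distances are permutation-equivariant even if axes flip
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        Dp = np.linalg.norm(Xp[:, None] - Xp[None, :], axis=2)
        assert np.allclose(Dp, D[np.ix_(perm, perm)], atol=1e-9)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            layout(np.array([[1.0, 0.2], [0.4, 1.0]]))

    def test_degenerate_rank_padded(self):
        S = np.ones((3, 3))
        X = layout(S)
        assert X.shape == (3, 2)
        assert np.allclose(X, 0.0)

    def test_eigenspace_oracle(self):
        # independent top-2 eigenreconstruction of the doubly centered Gram
        rng = np.random.default_rng(2)
        for n in (3, 4, 5):
            A = rng.uniform(0, 1, size=(n, n))
            S = np.clip((A + A.T) / 2, 0, 1)
            np.fill_diagonal(S, 1.0)
            X = layout(S)
            D = 1.0 - S
            np.fill_diagonal(D, 0.0)
            J = np.eye(n) - np.ones((n, n)) / n
            B = -0.5 * J @ (D**2) @ J
            vals, vecs = np.linalg.eigh((B + B.T) / 2)
            idx = np.argsort(vals)[::-1][:2]
            Y = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))
            Dx = np.linalg.norm(X[:, None] - X[None, :], axis=2)
            Dy = np.linalg.norm(Y[:, None] - Y[None, :], axis=2)
            assert np.allclose(Dx, Dy, atol=1e-9)


class TestSnapshot:
    def _archive(self):
        a = Archive()
        for i, (lemma, pol, n) in enumerate(
            [("a", 0.5, 3), ("b", -0.2, 2), ("c", 0.1, 4)]
        ):
            a.append(SentimentRecord(lemma, D1, pol, pol, n, "all"))
            a.append(
                SentimentRecord(
                    lemma,
                    D1 + datetime.timedelta(days=1),
                    pol / 2,
                    pol / 2,
                    n,
                    "all",
                )
            )
        return a

    def test_fields_composed_from_archive(self):
        archive = self._archive()
        tweets = _tweets([["a", "b"], ["a", "c"], ["b", "c"]])
        window = (D1, D1 + datetime.timedelta(days=1))
        snap = snapshot(archive, tweets, ["a", "b", "c"], window)
        by_lemma = {w[0]: w for w in snap.words}
        # polarity = last in window; frequency = sum of daily counts
        assert by_lemma["a"][3] == pytest.approx(0.25)
        assert by_lemma["a"][4] == 6
        assert by_lemma["b"][4] == 4
        # centroid at origin
        xs = np.array([[w[1], w[2]] for w in snap.words])
        assert np.allclose(xs.mean(axis=0), 0.0, atol=1e-9)

    def test_absent_word_excluded_with_warning(self, caplog):
        archive = self._archive()
        tweets = _tweets([["a", "b"]])
        with caplog.at_level("WARNING"):
            snap = snapshot(archive, tweets, ["a", "b", "ghost"], (D1, D1))
        assert {w[0] for w in snap.words} == {"a", "b"}
        assert any("ghost" in r.message for r in caplog.records)

    def test_too_few_words_rejected(self):
        archive = self._archive()
        with pytest.raises(ValueError):
            snapshot(archive, [], ["a", "ghost"], (D1, D1))

    def test_two_window_snapshots_diffable(self):
        archive = self._archive()
        tweets = _tweets([["a", "b"], ["a", "c"], ["b", "c"]])
        s1 = snapshot(archive, tweets, ["a", "b", "c"], (D1, D1))
        d2 = D1 + datetime.timedelta(days=1)
        s2 = snapshot(archive, tweets, ["a", "b", "c"], (d2, d2))
        assert [w[0] for w in s1.words] == [w[0] for w in s2.words]
        assert s1.words != s2.words  # polarity halves on day 2

    def test_json_round_trip_keys(self, tmp_path):
        import json

        archive = self._archive()
        tweets = _tweets([["a", "b"]])
        snap = snapshot(archive, tweets, ["a", "b"], (D1, D1))
        p = tmp_path / "snap.json"
        snap.to_json(p)
        data = json.loads(p.read_text())
        assert set(data) == {"window", "words"}
        assert {w["lemma"] for w in data["words"]} == {"a", "b"}


class TestFrequencyCloud:
    def test_empty(self):
        assert frequency_cloud([]) == []

    def test_counts_match_brute_force(self):
        tweets = _tweets([["a", "b", "a"], ["b"], ["c", "a"]])
        got = dict(frequency_cloud(tweets))
        assert got == {"a": 3, "b": 2, "c": 1}
        # descending order
        freqs = [f for _, f in frequency_cloud(tweets)]
        assert freqs == sorted(freqs, reverse=True)

    def test_extra_stopword_excluded(self):
        tweets = _tweets([["covid", "vacuna"], ["covid"]])
        got = frequency_cloud(tweets, stopwords={"covid"})
        assert got == [("vacuna", 1)]


class TestRenderingMaps:
    def test_color_endpoints(self):
        r_neg, g_neg, _ = polarity_to_color(-1.0)
        r_pos, g_pos, _ = polarity_to_color(1.0)
        assert r_neg > g_neg  # red at -1
        assert g_pos > r_pos  # green at +1

    def test_color_monotone(self):
        ps = np.linspace(-1, 1, 21)
        greenness = [polarity_to_color(p)[1] - polarity_to_color(p)[0] for p in ps]
        assert all(b >= a for a, b in zip(greenness, greenness[1:]))

    def test_size_monotone_affine_in_log(self):
        sizes = [frequency_to_size(f) for f in (0, 1, 10, 100)]
        assert all(b > a for a, b in zip(sizes, sizes[1:]))
        # affine in log1p: size(f) - base proportional to log1p(f)
        base = frequency_to_size(0)
        assert (frequency_to_size(10) - base) / np.log1p(10) == pytest.approx(
            (frequency_to_size(100) - base) / np.log1p(100)
        )

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            frequency_to_size(-1)

    def test_render_smoke(self, tmp_path):
        from driftlex.viz import render_frequency_cloud, render_snapshot, render_trends

        archive = TestSnapshot()._archive()
        tweets = _tweets([["a", "b"], ["a", "c"]])
        snap = snapshot(archive, tweets, ["a", "b", "c"], (D1, D1))
        render_snapshot(snap, tmp_path / "s.png")
        render_frequency_cloud([("a", 3), ("b", 1)], tmp_path / "f.png")
        render_trends({"a": [(D1, 0.1), (D1 + datetime.timedelta(days=1), 0.2)]},
                      tmp_path / "t.png")
        for name in ("s.png", "f.png", "t.png"):
            assert (tmp_path / name).stat().st_size > 0
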