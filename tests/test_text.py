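"""Natural-language pipeline: SRT binning, preprocessing, counting,
smoothing, tf-idf weighting, and NMF-LSA factorization."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbstates import text
from nbstates.srt import Cue, SRTParseError, format_srt, parse_srt
from nbstates.text import (
    NMFLSA,
    TokenTimeline,
    WordCountMatrix,
    build_word_count_matrix,
    fit_nmf_lsa,
    parse_timed_text,
    preprocess_tokens,
    smooth_counts,
    tfidf_transform,
    top_words,
)

SRT_SAMPLE = """1
00:00:01,000 --> 00:00:03,500
run forrest run

2
00:00:05,000 --> 00:00:05,900
stupid is
"""


class TestSrtFormat:
    def test_parse_timestamps_and_text(self):
        cues = parse_srt(SRT_SAMPLE)
        assert len(cues) == 2
        assert cues[0].start_seconds == 1.0
        assert cues[0].end_seconds == 3.5
        assert cues[0].text == "run forrest run"

    def test_round_trip(self):
        cues = parse_srt(SRT_SAMPLE)
        assert parse_srt(format_srt(cues)) == [
            Cue(c.index, c.start_seconds, c.end_seconds, c.text) for c in cues
        ]

    def test_malformed_timestamp_names_cue(self):
        bad = "1\n00:00:xx,000 --> 00:00:02,000\nhello\n"
        with pytest.raises(SRTParseError, match="cue 1"):
            parse_srt(bad)


class TestParseTimedText:
    def test_cue_spans_every_overlapped_bin(self):
        # interval-overlap oracle: [1.0, 3.5) meets [0,2) and [2,4) only
        tl = parse_timed_text(SRT_SAMPLE, tr_seconds=2.0, n_timepoints=4)
        assert tl.tokens[0] == ["run", "forrest", "run"]
        assert tl.tokens[1] == ["run", "forrest", "run"]
        assert tl.tokens[2] == ["stupid", "is"]
        assert tl.tokens[3] == []

    def test_empty_srt(self):
        tl = parse_timed_text("", tr_seconds=2.0, n_timepoints=5)
        assert tl.tokens == [[] for _ in range(5)]

    def test_out_of_range_cue_dropped_with_warning(self, caplog):
        srt = "1\n00:00:08,000 --> 00:00:09,000\nlate words\n"
        with caplog.at_level(logging.WARNING, logger="nbstates.text"):
            tl = parse_timed_text(srt, tr_seconds=2.0, n_timepoints=4)
        assert all(not b for b in tl.tokens)
        assert any("dropped" in r.message for r in caplog.records)


class TestPreprocess:
    def test_casefold_punctuation_stopwords(self):
        tl = TokenTimeline(1, 2.0, [["The", "DOG", "ran."]])
        out = preprocess_tokens(tl, stopwords={"the"})
        assert out.tokens[0] == ["dog", "ran"]

    def test_all_stopword_bin_empties(self):
        tl = TokenTimeline(1, 2.0, [["the", "a", "of"]])
        assert preprocess_tokens(tl).tokens[0] == []

    def test_idempotent(self):
        tl = TokenTimeline(2, 2.0, [["Hello,", "world!"], ["IT'S", "me"]])
        once = preprocess_tokens(tl)
        twice = preprocess_tokens(once)
        assert once.tokens == twice.tokens


class TestWordCountMatrix:
    def test_manual_count_oracle(self):
        tl = TokenTimeline(2, 2.0, [["a", "b", "a"], ["b"]])
        M = build_word_count_matrix(tl)
        assert M.vocabulary == ["a", "b"]
        assert M.values.tolist() == [[2.0, 1.0], [0.0, 1.0]]

    def test_empty_timeline(self):
        M = build_word_count_matrix(TokenTimeline(3, 2.0, [[], [], []]))
        assert M.values.shape == (3, 0)
        assert M.vocabulary == []

    def test_column_sums_are_corpus_frequencies(self, rng):
        words = ["w%d" % i for i in range(5)]
        bins = [
            [words[j] for j in rng.integers(0, 5, size=rng.integers(0, 8))]
            for _ in range(10)
        ]
        M = build_word_count_matrix(TokenTimeline(10, 2.0, bins))
        flat = [w for b in bins for w in b]
        for j, w in enumerate(M.vocabulary):
            assert M.values[:, j].sum() == flat.count(w)


def _smooth_oracle(values, half):
    """Direct-loop truncated mean."""
    T = values.shape[0]
    out = np.empty_like(values, dtype=float)
    for t in range(T):
        lo, hi = max(0, t - half), min(T, t + half + 1)
        out[t] = values[lo:hi].mean(axis=0)
    return out


class TestSmoothing:
    def test_subminute_window_is_identity(self):
        M = WordCountMatrix(np.arange(8.0).reshape(4, 2), ["a", "b"])
        out = smooth_counts(M, window_minutes=0.01, tr_seconds=2.0)
        assert np.array_equal(out.values, M.values)

    def test_hand_computed_center_mean(self):
        col = np.array([[0.0], [3.0], [0.0], [0.0], [3.0]])
        M = WordCountMatrix(col, ["x"])
        # window of 2 bins per side at TR=2 needs 4 s half-window = 8 s window
        out = smooth_counts(M, window_minutes=4.0 / 60.0, tr_seconds=2.0)
        assert out.values[1, 0] == pytest.approx(1.0)

    def test_edge_truncation(self):
        col = np.array([[2.0], [4.0], [0.0], [0.0]])
        out = smooth_counts(WordCountMatrix(col, ["x"]), 4.0 / 60.0, 2.0)
        assert out.values[0, 0] == pytest.approx(3.0)  # mean of bins 0-1 only

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        t=st.integers(3, 30),
        v=st.integers(1, 4),
        half=st.integers(0, 10),
        seed=st.integers(0, 100),
    )
    def test_matches_direct_loop_oracle(self, t, v, half, seed):
        values = np.random.default_rng(seed).uniform(size=(t, v))
        M = WordCountMatrix(values, [f"w{i}" for i in range(v)])
        window_minutes = half * 2 * 2.0 / 60.0  # half bins at TR=2
        out = smooth_counts(M, window_minutes, 2.0)
        np.testing.assert_allclose(out.values, _smooth_oracle(values, half), atol=1e-12)


def _tfidf_oracle(values):
    """Naive double-loop evaluation of the tf-idf weighting."""
    T, V = values.shape
    out = np.zeros_like(values, dtype=float)
    for w in range(V):
        n_w = sum(1 for t in range(T) if values[t, w] > 0)
        for t in range(T):
            denom = values[t].sum()
            tf = values[t, w] / denom if denom > 0 else 0.0
            out[t, w] = tf * np.log(T / (1.0 + n_w))
    return out


class TestTfidf:
    def test_hand_evaluated_weight(self):
        # T=4, word present in 2 bins, tf = 2/4 at bin 1 -> 0.5 ln(4/3)
        values = np.array(
            [[0.0, 1.0], [2.0, 2.0], [0.0, 1.0], [2.0, 1.0]], dtype=float
        )
        out = tfidf_transform(WordCountMatrix(values, ["u", "v"]))
        assert out.values[1, 0] == pytest.approx(0.5 * np.log(4.0 / 3.0))

    def test_absent_word_weight_zero(self):
        values = np.array([[0.0, 2.0], [1.0, 1.0]])
        out = tfidf_transform(WordCountMatrix(values, ["u", "v"]))
        assert out.values[0, 0] == 0.0

    def test_ubiquitous_word_goes_negative(self):
        values = np.ones((4, 1))
        out = tfidf_transform(WordCountMatrix(values, ["u"]))
        assert np.all(out.values < 0)  # idf = ln(T/(T+1)) < 0, kept as printed

    def test_zero_row_maps_to_zero_row(self):
        values = np.array([[0.0, 0.0], [1.0, 2.0]])
        out = tfidf_transform(WordCountMatrix(values, ["u", "v"]))
        assert np.all(out.values[0] == 0.0)

    def test_matches_naive_double_loop(self, rng):
        for _ in range(5):
            values = rng.uniform(size=(20, 10)) * (rng.uniform(size=(20, 10)) > 0.4)
            out = tfidf_transform(WordCountMatrix(values, [f"w{i}" for i in range(10)]))
            np.testing.assert_allclose(out.values, _tfidf_oracle(values), atol=1e-12)


class TestNMFLSA:
    def test_exact_rank2_identity(self):
        est = NMFLSA(n_components=2, max_iter=2000, tol=0.0, random_state=0)
        est.fit(np.eye(2))
        assert est.reconstruction_err_ <= 1e-6

    def test_factors_nonnegative_and_rows_unit_norm(self, rng):
        M = rng.uniform(size=(15, 8))
        est = NMFLSA(n_components=4, random_state=0).fit(M)
        W = est._W
        assert W.min() >= 0 and est.components_.min() >= 0
        np.testing.assert_allclose(
            np.linalg.norm(est.components_, axis=1), 1.0, atol=1e-8
        )

    def test_planted_nonnegative_rank3(self, rng):
        W0 = rng.uniform(size=(30, 3))
        H0 = rng.uniform(size=(3, 12))
        M = W0 @ H0  # direct-multiplication oracle defines the target
        est = NMFLSA(n_components=3, max_iter=5000, tol=1e-14, random_state=1).fit(M)
        assert est.reconstruction_err_ / np.linalg.norm(M) <= 1e-3

    def test_objective_monotone_nonincreasing(self, rng):
        M = rng.uniform(size=(25, 10))
        est = NMFLSA(n_components=5, max_iter=300, tol=0.0, random_state=2).fit(M)
        tr = est.objective_trace_
        assert all(b <= a + 1e-10 for a, b in zip(tr, tr[1:]))

    def test_dimension_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            NMFLSA(n_components=5).fit(np.ones((3, 4)))

    def test_close_to_sklearn_reference(self, rng):
        # independent implementation reaches a comparable objective
        from sklearn.decomposition import NMF

        M = rng.uniform(size=(40, 15))
        ours = NMFLSA(n_components=4, max_iter=2000, tol=1e-12, random_state=0).fit(M)
        ref = NMF(n_components=4, solver="mu", max_iter=2000, init="random",
                  random_state=0, tol=1e-12).fit(M)
        ref_err = np.linalg.norm(M - ref.transform(M) @ ref.components_)
        assert ours.reconstruction_err_ <= ref_err * 1.05


class TestTopWords:
    def _contexts(self):
        H = np.array([[0.1, 0.5, 0.5, 0.2], [0.9, 0.0, 0.1, 0.0]])
        H = H / np.linalg.norm(H, axis=1, keepdims=True)
        W = np.ones((3, 2))
        return text.SemanticContexts(W, H, ["apple", "pear", "plum", "quince"], 0.0)

    def test_saturation_returns_all(self):
        assert len(top_words(self._contexts(), 0, 99)) == 4

    def test_unique_maximum_first_and_tie_lexicographic(self):
        ranked = top_words(self._contexts(), 0, 4)
        assert ranked[0] == "pear"  # tie with plum broken lexicographically
        assert ranked[1] == "plum"

    def test_matches_full_sort_oracle(self, rng):
        vocab = [f"w{i:02d}" for i in range(12)]
        H = rng.uniform(size=(2, 12))
        ctx = text.SemanticContexts(np.ones((3, 2)), H, vocab, 0.0)
        expected = [w for _, w in sorted(zip(-H[1], vocab))]
        assert top_words(ctx, 1, 12) == expected


class TestGridSearchWindow:
    def test_singleton_candidate_selected(self, rng):
        M = WordCountMatrix(rng.uniform(size=(30, 6)), [f"w{i}" for i in range(6)])
        gamma = rng.uniform(size=(30, 2))
        sel, table = text.grid_search_window(M, [2.0], gamma, s=2, seed=0, max_iter=50)
        assert sel == 2.0
        assert len(table) == 1

    def test_one_table_row_per_candidate(self, rng):
        M = WordCountMatrix(rng.uniform(size=(30, 6)), [f"w{i}" for i in range(6)])
        gamma = rng.uniform(size=(30, 2))
        _, table = text.grid_search_window(
            M, [1.0, 2.0, 4.0], gamma, s=2, seed=0, max_iter=50
        )
        assert list(table["window_minutes"]) == [1.0, 2.0, 4.0]

    def test_empty_candidates_error(self, rng):
        M = WordCountMatrix(rng.uniform(size=(10, 4)), list("abcd"))
        with pytest.raises(ValueError):
            text.grid_search_window(M, [], np.ones((10, 2)), s=2)
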