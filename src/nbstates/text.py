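"""Timed text to semantic-context expressions.

The natural-language pipeline: parse SubRip cues onto the TR grid,
case-fold / strip punctuation / remove stop words, build a bag-of-words
timepoint-by-vocabulary count matrix, smooth it with a centered boxcar
window, weight it by tf-idf

    tfidf(w, t) = f_{w,t} / sum_{w'} f_{w',t} * ln(T / (1 + n_w)),

with ``n_w`` the number of timepoints whose bag of words contains ``w``,
and factor the result with nonnegativity-constrained latent semantic
analysis (NMF-LSA): ``M ~= W H`` with ``W, H >= 0``.  Each column of W is
the per-timepoint expression of one semantic context; the matching H row
holds its word weights.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._utils import check_matrix
from .srt import parse_srt

logger = logging.getLogger(__name__)

# Compact default English stop-word list (the full list is a configurable
# input; the study corpus is German, so no single built-in list is canonical).
DEFAULT_STOPWORDS = frozenset(
    """a about above after again all am an and any are as at be because been
    before being below between both but by could did do does doing down during
    each few for from further had has have having he her here hers herself him
    himself his how i if in into is it its itself just me more most my myself
    no nor not now of off on once only or other our ours ourselves out over own
    same she should so some such than that the their theirs them themselves
    then there these they this those through to too under until up very was we
    were what when where which while who whom why will with you your yours
    yourself yourselves""".split()
)

_PUNCT_TABLE = str.maketrans("", "", string.punctuation + "¡¿«»“”‘’–—…")


@dataclass
class TokenTimeline:
    """Per-timepoint lists of lowercase tokens on the TR grid."""

    n_timepoints: int
    tr_seconds: float
    tokens: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.tokens) != self.n_timepoints:
            raise ValueError(
                f"got {len(self.tokens)} token bins for {self.n_timepoints} timepoints"
            )


@dataclass
class WordCountMatrix:
    """Timepoints x vocabulary matrix at one pipeline stage.

    ``stage`` is one of ``raw`` (integer counts), ``smoothed`` (boxcar means)
    or ``tfidf`` (weights; may be negative for ubiquitous words).
    """

    values: np.ndarray
    vocabulary: list[str]
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = check_matrix(self.values, "values")
        if self.values.shape[1] != len(self.vocabulary):
            raise ValueError("vocabulary length does not match column count")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("vocabulary entries must be unique")

    @property
    def T(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.vocabulary)


@dataclass
class SemanticContexts:
    """NMF-LSA factors: expressions ``W`` (T x s) and word weights ``H`` (s x V)."""

    W: np.ndarray
    H: np.ndarray
    vocabulary: list[str]
    reconstruction_error: float
    objective_trace: list[float] = field(default_factory=list)
    n_clipped: int = 0
    seed: int | None = None

    @property
    def s(self) -> int:
        return self.W.shape[1]


def parse_timed_text(
    srt_text: str, tr_seconds: float, n_timepoints: int
) -> TokenTimeline:
    """Bin SubRip cues onto the TR grid.

    A cue's tokens are assigned to every bin ``[t*TR, (t+1)*TR)`` its time
    span overlaps with positive measure; cues that start at or beyond the end
    of the grid are dropped with a warning.
    """
    cues = parse_srt(srt_text)
    tokens: list[list[str]] = [[] for _ in range(n_timepoints)]
    horizon = n_timepoints * tr_seconds
    n_dropped = 0
    for cue in cues:
        if cue.start_seconds >= horizon:
            n_dropped += 1
            continue
        cue_tokens = cue.text.split()
        first = int(np.floor(cue.start_seconds / tr_seconds))
        # half-open overlap: the bin containing end_seconds is included only
        # if the cue extends into it with positive measure
        last = int(np.ceil(cue.end_seconds / tr_seconds)) - 1
        last = max(last, first)
        for t in range(first, min(last, n_timepoints - 1) + 1):
            tokens[t].extend(cue_tokens)
    if n_dropped:
        logger.warning(
            "dropped %d cue(s) starting past the last timepoint bin", n_dropped
        )
    return TokenTimeline(n_timepoints, tr_seconds, tokens)


def preprocess_tokens(
    timeline: TokenTimeline, stopwords=DEFAULT_STOPWORDS
) -> TokenTimeline:
    """Case-fold, strip punctuation, and remove stop words. Idempotent."""
    stopwords = frozenset(stopwords)
    cleaned = []
    for bin_tokens in timeline.tokens:
        out = []
        for tok in bin_tokens:
            tok = tok.lower().translate(_PUNCT_TABLE)
            if tok and tok not in stopwords:
                out.append(tok)
        cleaned.append(out)
    return TokenTimeline(timeline.n_timepoints, timeline.tr_seconds, cleaned)


def build_word_count_matrix(timeline: TokenTimeline) -> WordCountMatrix:
    """Bag-of-words counts: values[t, w] = occurrences of word w in bin t."""
    vocabulary = sorted({tok for bin_tokens in timeline.tokens for tok in bin_tokens})
    index = {w: j for j, w in enumerate(vocabulary)}
    values = np.zeros((timeline.n_timepoints, len(vocabulary)))
    for t, bin_tokens in enumerate(timeline.tokens):
        for tok in bin_tokens:
            values[t, index[tok]] += 1.0
    return WordCountMatrix(values, vocabulary, stage="raw")


def smooth_counts(
    M: WordCountMatrix, window_minutes: float, tr_seconds: float
) -> WordCountMatrix:
    """Centered boxcar mean over +-window/2, truncated at the timeline edges.

    The half window in bins is ``floor((window/2) / TR)``; a window shorter
    than one TR is the identity.
    """
    if window_minutes < 0:
        raise ValueError("window_minutes must be nonnegative")
    half = int(np.floor(window_minutes * 60.0 / 2.0 / tr_seconds))
    values = smooth_rows(M.values, half)
    return WordCountMatrix(values, list(M.vocabulary), stage="smoothed")


def smooth_rows(values: np.ndarray, half_window_bins: int) -> np.ndarray:
    """Truncated-mean boxcar smoothing along axis 0 (cumulative-sum trick)."""
    values = check_matrix(values)
    h = int(half_window_bins)
    if h <= 0:
        return values.copy()
    T = values.shape[0]
    csum = np.vstack([np.zeros((1, values.shape[1])), np.cumsum(values, axis=0)])
    lo = np.maximum(np.arange(T) - h, 0)
    hi = np.minimum(np.arange(T) + h + 1, T)
    window_sums = csum[hi] - csum[lo]
    counts = (hi - lo).astype(float)[:, None]
    return window_sums / counts


def tfidf_transform(
    M: WordCountMatrix, occupancy_from: WordCountMatrix | None = None
) -> WordCountMatrix:
    """tf-idf weighting with timepoints as documents.

    tf is the within-bin relative frequency; idf = ln(T / (1 + n_w)) with
    ``n_w`` the number of bins whose count of ``w`` is positive.  When the
    input has been window-smoothed, pass the raw count matrix as
    ``occupancy_from`` so that n_w reflects actual word occurrences: a
    boxcar several minutes wide bridges the gaps of any recurring word,
    which would otherwise drive its idf to ~0 and erase exactly the
    recurring themes the decomposition is meant to find.  All-zero bins map
    to zero rows.  idf is negative for words present in ~all bins; such
    weights are kept as computed (downstream NMF clips them).
    """
    values = M.values
    if not np.any(values):
        raise ValueError("word count matrix has no nonzero row")
    T = values.shape[0]
    row_sums = values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tf = np.where(row_sums > 0, values / np.where(row_sums == 0, 1.0, row_sums), 0.0)
    occ = M if occupancy_from is None else occupancy_from
    if occ.values.shape != values.shape or occ.vocabulary != M.vocabulary:
        raise ValueError("occupancy_from must share shape and vocabulary with M")
    n_w = (occ.values > 0).sum(axis=0)
    idf = np.log(T / (1.0 + n_w))
    return WordCountMatrix(tf * idf[None, :], list(M.vocabulary), stage="tfidf")


class NMFLSA(TransformerMixin, BaseEstimator):
    """Nonnegativity-constrained LSA via multiplicative-update NMF.

    Minimizes ``||M - W H||_F^2`` with ``W, H >= 0`` by Lee-Seung
    multiplicative updates from a seeded uniform initialization scaled by
    ``sqrt(mean(M) / s)``.  After convergence H rows are scaled to unit
    Euclidean norm (scale absorbed into W) and contexts are sorted by total
    expression, descending.

    Parameters
    ----------
    n_components : number of semantic contexts ``s`` (study default 200).
    max_iter : multiplicative-update cap (study default 500).
    tol : relative objective-change stopping threshold.
    random_state : seed for the initialization.

    Attributes
    ----------
    components_ : (s, V) word-weight matrix H, unit-norm rows.
    reconstruction_err_ : final Frobenius reconstruction error.
    objective_trace_ : per-iteration squared-error objective (nonincreasing).
    n_clipped_ : number of negative input entries clipped to 0.
    """

    def __init__(self, n_components=200, max_iter=500, tol=1e-6, random_state=0):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        M = check_matrix(np.asarray(X, dtype=float), "M")
        n_neg = int((M < 0).sum())
        if n_neg:
            logger.info("clipping %d negative entries to 0 before NMF", n_neg)
            M = np.clip(M, 0.0, None)
        T, V = M.shape
        s = int(self.n_components)
        if s > min(T, V):
            raise ValueError(f"n_components={s} exceeds min(T, V)={min(T, V)}")
        rng = np.random.default_rng(self.random_state)
        scale = np.sqrt(max(M.mean(), np.finfo(float).tiny) / s)
        W = scale * rng.uniform(size=(T, s))
        H = scale * rng.uniform(size=(s, V))
        eps = 1e-12
        trace = []
        prev = None
        for _ in range(int(self.max_iter)):
            H *= (W.T @ M) / (W.T @ W @ H + eps)
            W *= (M @ H.T) / (W @ (H @ H.T) + eps)
            obj = float(np.linalg.norm(M - W @ H) ** 2)
            trace.append(obj)
            if prev is not None and prev - obj <= self.tol * max(prev, eps):
                break
            prev = obj
        # carry H-row scale into W; guard all-zero components
        norms = np.linalg.norm(H, axis=1)
        safe = np.where(norms > 0, norms, 1.0)
        H /= safe[:, None]
        W *= safe[None, :]
        order = np.argsort(-W.sum(axis=0), kind="stable")
        self.components_ = H[order]
        self.reconstruction_err_ = float(np.sqrt(trace[-1]))
        self.objective_trace_ = trace
        self.n_clipped_ = n_neg
        self.n_features_in_ = V
        self._W = W[:, order]
        return self._W

    def transform(self, X):
        """Nonnegative least-squares-style projection of new rows onto H."""
        check_is_fitted(self, "components_")
        M = np.clip(check_matrix(np.asarray(X, dtype=float)), 0.0, None)
        H = self.components_
        rng = np.random.default_rng(self.random_state)
        W = rng.uniform(size=(M.shape[0], H.shape[0])) * np.sqrt(
            max(M.mean(), np.finfo(float).tiny) / H.shape[0]
        )
        eps = 1e-12
        HHt = H @ H.T
        for _ in range(200):
            W *= (M @ H.T) / (W @ HHt + eps)
        return W


def fit_nmf_lsa(
    M: WordCountMatrix,
    s: int = 200,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SemanticContexts:
    """Factor a (tf-idf) word count matrix into ``s`` semantic contexts."""
    est = NMFLSA(n_components=s, max_iter=max_iter, tol=tol, random_state=seed)
    W = est.fit_transform(M.values)
    return SemanticContexts(
        W=W,
        H=est.components_,
        vocabulary=list(M.vocabulary),
        reconstruction_error=est.reconstruction_err_,
        objective_trace=est.objective_trace_,
        n_clipped=est.n_clipped_,
        seed=seed,
    )


def top_words(contexts: SemanticContexts, context_index: int, k: int) -> list[str]:
    """The k words with the largest H weights, descending; ties lexicographic."""
    if not 0 <= context_index < contexts.s:
        raise IndexError(f"context index {context_index} out of range")
    row = contexts.H[context_index]
    order = sorted(range(len(row)), key=lambda j: (-row[j], contexts.vocabulary[j]))
    return [contexts.vocabulary[j] for j in order[: int(k)]]


def grid_search_window(
    M_raw: WordCountMatrix,
    candidate_windows: list[float],
    state_presence: np.ndarray,
    s: int,
    seed: int = 0,
    tr_seconds: float = 2.0,
    top_k: int = 10,
    max_iter: int = 500,
):
    """Select the smoothing window maximizing the mean top-k link strength.

    For each candidate window (minutes): smooth -> tf-idf -> NMF -> correlate
    W against the supplied state presence, and record the mean and max of the
    per-state top-k link strengths.  Returns ``(selected_window, table)``.
    """
    from .linkage import correlation_matrix, top_k_link_strength

    if len(candidate_windows) == 0:
        raise ValueError("candidate_windows must be nonempty")
    gamma = check_matrix(state_presence, "state_presence")
    rows = []
    for w in candidate_windows:
        smoothed = smooth_counts(M_raw, w, tr_seconds)
        weighted = tfidf_transform(smoothed, occupancy_from=M_raw)
        ctx = fit_nmf_lsa(weighted, s=s, seed=seed, max_iter=max_iter)
        P = correlation_matrix(gamma, ctx.W)
        per_state, model_index = top_k_link_strength(P, k=top_k)
        top1 = float(P.max(axis=0).mean())
        rows.append(
            {
                "window_minutes": float(w),
                "mean_top_k_link": model_index,
                "max_link": top1,
            }
        )
    table = pd.DataFrame(rows)
    selected = float(table.loc[table["mean_top_k_link"].idxmax(), "window_minutes"])
    return selected, table


def serialize_contexts(contexts: SemanticContexts, out_dir) -> None:
    """Write W and H as TSV plus a JSON metadata sidecar."""
    import json
    from pathlib import Path

    from ._utils import write_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = [f"context_{j:03d}" for j in range(contexts.s)]
    write_tsv(pd.DataFrame(contexts.W, columns=names), out / "contexts_W.tsv")
    write_tsv(
        pd.DataFrame(contexts.H, index=names, columns=contexts.vocabulary),
        out / "contexts_H.tsv",
        index=True,
    )
    meta = {
        "s": contexts.s,
        "seed": contexts.seed,
        "reconstruction_error": contexts.reconstruction_error,
        "n_clipped": contexts.n_clipped,
    }
    (out / "contexts_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
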