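"""Group-level state-aligned PLS signatures.

Subjects' independently fitted HMM state labels are matched to a template
subject with the Hungarian algorithm (cost = distance between state mean
vectors), the movie timeline is partitioned by hard-assigned state, the
per-state brain blocks G_k and external-description blocks E_k are
concatenated across subjects, and a single-component PLS regression per
state extracts the paired description/brain loading vectors maximizing
their cross-covariance, validated by blocked 20-fold cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._utils import check_matrix
from .hmm import HMMSolution, hard_assign

logger = logging.getLogger(__name__)


@dataclass
class StateAlignment:
    """Permutation matching one subject's states to the template's."""

    subject_id: object
    permutation: list[int]  # permutation[src_state] = template state
    cost: float


@dataclass
class GroupSignature:
    """One state's PLS component."""

    state: int
    description_loadings: np.ndarray  # (P,)
    brain_loadings: np.ndarray  # (R,)
    scores_description: np.ndarray
    scores_brain: np.ndarray
    train_covariance: float
    train_correlation: float
    cv_correlations: np.ndarray | None = None
    cv_mean: float | None = None
    extras: dict = field(default_factory=dict)


def align_states(
    template: HMMSolution, other: HMMSolution, include_cov: bool = False
) -> StateAlignment:
    """Hungarian matching of ``other``'s states onto ``template``'s.

    Cost between states is the Euclidean distance of the mean vectors
    (optionally plus the Frobenius distance of the covariances).
    """
    if template.n != other.n:
        raise ValueError(f"state counts differ: {template.n} vs {other.n}")
    n = template.n
    cost = np.empty((n, n))
    for i in range(n):  # rows: other's states
        for j in range(n):  # cols: template states
            d = float(np.linalg.norm(other.means[i] - template.means[j]))
            if include_cov:
                d += float(np.linalg.norm(other.covars[i] - template.covars[j]))
            cost[i, j] = d
    rows, cols = linear_sum_assignment(cost)
    permutation = [0] * n
    for i, j in zip(rows, cols):
        permutation[i] = int(j)
    return StateAlignment(
        subject_id=getattr(other, "subject_id", None),
        permutation=permutation,
        cost=float(cost[rows, cols].sum()),
    )


def apply_alignment(solution: HMMSolution, alignment: StateAlignment) -> HMMSolution:
    """Relabel a solution's states into template order."""
    perm = alignment.permutation
    inv = np.argsort(perm)  # inv[template_state] = source state
    gamma = solution.gamma[:, inv]
    trans = solution.transmat[np.ix_(inv, inv)]
    return HMMSolution(
        n=solution.n,
        startprob=solution.startprob[inv],
        transmat=trans,
        means=solution.means[inv],
        covars=solution.covars[inv],
        gamma=gamma,
        log_likelihood=solution.log_likelihood,
        seed=solution.seed,
        n_iter=solution.n_iter,
        converged=solution.converged,
        loglik_trace=list(solution.loglik_trace),
        link_index=solution.link_index,
    )


def partition_by_state(states, series) -> list[np.ndarray]:
    """Route each timepoint's row to its hard-assigned state.

    ``states`` is either a length-T hard sequence or a T x n gamma matrix.
    Returns one row-block per state (possibly empty); row counts sum to T.
    """
    states = np.asarray(states)
    series = check_matrix(series, "series")
    if states.ndim == 2:
        n = states.shape[1]
        seq = hard_assign(states)
    else:
        seq = states.astype(int)
        n = int(seq.max()) + 1 if seq.size else 0
    if seq.size != series.shape[0]:
        raise ValueError("state sequence and series must share T")
    return [series[seq == k] for k in range(n)]


def concat_group(per_subject_blocks: list[list[np.ndarray]]):
    """Row-stack each state's blocks across subjects, in subject order.

    ``per_subject_blocks[i][k]`` is subject i's block for state k.  Returns
    ``(stacked, subject_labels)`` where both are per-state lists; the labels
    record each row's subject index for fold construction.
    """
    if not per_subject_blocks:
        raise ValueError("no subjects given")
    n = len(per_subject_blocks[0])
    if any(len(blocks) != n for blocks in per_subject_blocks):
        raise ValueError("subjects disagree on the number of states")
    ncols = {b.shape[1] for blocks in per_subject_blocks for b in blocks if b.size}
    if len(ncols) > 1:
        raise ValueError(f"subjects disagree on column layout: {sorted(ncols)}")
    stacked, labels = [], []
    for k in range(n):
        blocks = [np.atleast_2d(s[k]) for s in per_subject_blocks]
        blocks = [b.reshape(0, max(ncols)) if b.size == 0 else b for b in blocks]
        stacked.append(np.vstack(blocks))
        labels.append(
            np.concatenate(
                [np.full(b.shape[0], i) for i, b in enumerate(blocks)]
            ).astype(int)
        )
    return stacked, labels


class PLS1(BaseEstimator):
    """One-component partial least squares by power iteration.

    Finds unit weight vectors u (descriptions) and v (brain) maximizing
    ``cov(E u, G v)`` — the dominant singular pair of the centered
    cross-covariance E_c^T G_c — via alternating power iteration.
    Description columns are standardized by default (mixed scales of
    semantic expressions and IOA values); the sign convention makes the
    largest-|entry| description weight positive.
    """

    def __init__(self, scale_descriptions: bool = True, tol: float = 1e-10,
                 max_iter: int = 1000):
        self.scale_descriptions = scale_descriptions
        self.tol = tol
        self.max_iter = max_iter

    def _prep_E(self, E: np.ndarray) -> np.ndarray:
        Ec = E - self.E_mean_
        if self.scale_descriptions:
            Ec = Ec / self.E_scale_
        return Ec

    def fit(self, E, G):
        E = check_matrix(E, "E")
        G = check_matrix(G, "G")
        if E.shape[0] != G.shape[0]:
            raise ValueError("E and G must share rows")
        if E.shape[0] <= 2:
            raise ValueError("need more than 2 samples")
        self.E_mean_ = E.mean(axis=0)
        sd = E.std(axis=0)
        self.E_scale_ = np.where(sd == 0, 1.0, sd)
        self.G_mean_ = G.mean(axis=0)
        Ec = self._prep_E(E)
        Gc = G - self.G_mean_
        C = Ec.T @ Gc
        rng = np.random.default_rng(0)
        u = rng.standard_normal(C.shape[0])
        u /= np.linalg.norm(u)
        for _ in range(int(self.max_iter)):
            v = C.T @ u
            nv = np.linalg.norm(v)
            if nv == 0:
                break
            v /= nv
            u_new = C @ v
            nu = np.linalg.norm(u_new)
            if nu == 0:
                break
            u_new /= nu
            if np.linalg.norm(u_new - u) < self.tol:
                u = u_new
                break
            u = u_new
        v = C.T @ u
        nv = np.linalg.norm(v)
        v = v / nv if nv > 0 else v
        j = int(np.argmax(np.abs(u)))
        if u[j] < 0:
            u, v = -u, -v
        self.x_weights_ = u
        self.y_weights_ = v
        x = Ec @ u
        y = Gc @ v
        self.x_scores_ = x
        self.y_scores_ = y
        self.covariance_ = float(x @ y / (len(x) - 1))
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(x, y)[0, 1]
        self.train_correlation_ = float(r) if np.isfinite(r) else 0.0
        return self

    def transform(self, E, G):
        check_is_fitted(self, "x_weights_")
        E = check_matrix(E, "E")
        G = check_matrix(G, "G")
        return self._prep_E(E) @ self.x_weights_, (G - self.G_mean_) @ self.y_weights_


def fit_pls1(E_k, G_k, state: int = 0, scale_descriptions: bool = True) -> GroupSignature:
    """Fit the single most explanatory description-brain signature."""
    model = PLS1(scale_descriptions=scale_descriptions).fit(E_k, G_k)
    return GroupSignature(
        state=state,
        description_loadings=model.x_weights_,
        brain_loadings=model.y_weights_,
        scores_description=model.x_scores_,
        scores_brain=model.y_scores_,
        train_covariance=model.covariance_,
        train_correlation=model.train_correlation_,
    )


def crossval_pls(
    E_k,
    G_k,
    subject_index,
    n_folds: int = 20,
    seed: int = 0,
    scale_descriptions: bool = True,
):
    """Blocked per-subject k-fold CV of the one-component PLS.

    Each subject's state-specific rows are split into ``n_folds`` contiguous
    blocks; fold f's test set concatenates block f across subjects.  Returns
    ``(fold_correlations, mean)`` of the Pearson r between the two held-out
    latent scores.
    """
    E_k = check_matrix(E_k, "E_k")
    G_k = check_matrix(G_k, "G_k")
    subject_index = np.asarray(subject_index, dtype=int)
    N = E_k.shape[0]
    if subject_index.size != N:
        raise ValueError("subject_index must label every row")
    if N < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} rows, got {N}")
    fold_of_row = np.empty(N, dtype=int)
    for subj in np.unique(subject_index):
        rows = np.flatnonzero(subject_index == subj)
        if rows.size < n_folds:
            warnings.warn(
                f"subject {subj} contributes only {rows.size} rows to this "
                f"state; its rows are spread over the first folds"
            )
        for f, chunk in enumerate(np.array_split(rows, n_folds)):
            fold_of_row[chunk] = f
    rs = []
    for f in range(int(n_folds)):
        test = fold_of_row == f
        train = ~test
        if test.sum() < 2 or train.sum() <= 2:
            rs.append(np.nan)
            continue
        model = PLS1(scale_descriptions=scale_descriptions).fit(
            E_k[train], G_k[train]
        )
        x, y = model.transform(E_k[test], G_k[test])
        if np.std(x) == 0 or np.std(y) == 0:
            rs.append(0.0)
            continue
        rs.append(float(np.corrcoef(x, y)[0, 1]))
    rs = np.asarray(rs)
    return rs, float(np.nanmean(rs))


def signature_report(
    signature: GroupSignature,
    top_k: int = 10,
    contexts=None,
    annotation_names=None,
    annotation_categories=None,
    n_semantic: int | None = None,
    pca_models: dict | None = None,
    limbic_slices: dict | None = None,
    brain_labels=None,
) -> dict:
    """Structured summary of one group signature.

    The description block is split into semantic contexts (first
    ``n_semantic`` entries of E's columns) and annotations; annotations are
    reported per category; limbic PC loadings are back-projected to
    subregion space through the supplied :class:`SharedHemispherePCA`
    models (``limbic_slices`` maps structure -> slice into brain loadings).
    """
    d = signature.description_loadings
    P = d.size
    if n_semantic is None:
        n_semantic = P if annotation_names is None else P - len(annotation_names)
    report: dict = {"state": signature.state}
    sem = d[:n_semantic]
    order = np.argsort(-np.abs(sem), kind="stable")[: min(top_k, n_semantic)]
    top_contexts = []
    for j in order:
        entry = {"context": int(j), "loading": float(sem[j])}
        if contexts is not None:
            from .text import top_words

            entry["top_words"] = top_words(contexts, int(j), 5)
        top_contexts.append(entry)
    report["top_semantic_contexts"] = top_contexts
    if annotation_names is not None:
        ann = d[n_semantic:]
        if len(annotation_names) != ann.size:
            raise ValueError("annotation names do not match loading length")
        cats = annotation_categories or {a: "other" for a in annotation_names}
        by_cat: dict[str, list] = {}
        for name, value in zip(annotation_names, ann):
            by_cat.setdefault(cats.get(name, "other"), []).append(
                {"annotation": name, "loading": float(value)}
            )
        for cat in by_cat:
            by_cat[cat].sort(key=lambda e: -abs(e["loading"]))
            by_cat[cat] = by_cat[cat][:top_k]
        report["top_annotations_by_category"] = by_cat
    v = signature.brain_loadings
    if brain_labels is not None:
        report["brain_loadings"] = {
            str(lbl): float(x) for lbl, x in zip(brain_labels, v)
        }
    else:
        report["brain_loadings"] = [float(x) for x in v]
    if pca_models and limbic_slices:
        back = {}
        for structure, sl in limbic_slices.items():
            back[structure] = [
                float(x)
                for x in pca_models[structure].inverse_transform_loadings(v[sl])
            ]
        report["limbic_subregion_loadings"] = back
    report["cv_mean_correlation"] = signature.cv_mean
    return report
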