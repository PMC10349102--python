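"""Gaussian-emission hidden Markov modeling of brain-state dynamics.

A first-order chain over n hidden states with time-invariant transition
matrix Theta (rows P(S_t = k | S_{t-1} = l)) and a full-covariance
multivariate-Gaussian observation model per state,

    x_t | S_t = k  ~  N(mu_k, Sigma_k).

Inference is exact forward-backward with per-step scaling; fitting is
Baum-Welch EM with a guaranteed nondecreasing log-likelihood.  Training
follows the study protocol: many restarts from randomized initializations
per series, keeping the restart whose state-presence trajectories show the
strongest mean top-k correlation with the semantic-context expressions.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._utils import check_matrix, spawn_seeds

logger = logging.getLogger(__name__)


@dataclass
class HMMSolution:
    """A fitted per-subject, per-combination HMM."""

    n: int
    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray  # (n, R)
    covars: np.ndarray  # (n, R, R)
    gamma: np.ndarray  # (T, n) posterior state presence
    log_likelihood: float
    seed: int | None = None
    n_iter: int = 0
    converged: bool = False
    loglik_trace: list[float] = field(default_factory=list)
    link_index: float | None = None
    restart_link_indices: list[float] = field(default_factory=list)

    @property
    def R(self) -> int:
        return self.means.shape[1]


def _log_mvn_density(X: np.ndarray, means: np.ndarray, covars: np.ndarray) -> np.ndarray:
    """(T, n) log N(x_t; mu_k, Sigma_k) via Cholesky solves."""
    T, R = X.shape
    n = means.shape[0]
    out = np.empty((T, n))
    const = -0.5 * R * np.log(2.0 * np.pi)
    for k in range(n):
        try:
            L = np.linalg.cholesky(covars[k])
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"covariance of state {k} is not SPD") from exc
        diff = X - means[k]
        z = np.linalg.solve(L, diff.T)
        out[:, k] = const - np.log(np.diag(L)).sum() - 0.5 * (z**2).sum(axis=0)
    return out


def forward_backward(series, startprob, transmat, means, covars):
    """Exact posterior state marginals and log-likelihood.

    Scaled alpha/beta recursions; safe for T ~ 3500, R up to ~30.
    Returns ``(gamma, log_likelihood)``.
    """
    gamma, loglik, _ = _forward_backward_full(
        check_matrix(series, "series"),
        np.asarray(startprob, float),
        np.asarray(transmat, float),
        np.asarray(means, float),
        np.asarray(covars, float),
    )
    return gamma, loglik


def _forward_backward_full(X, pi, A, means, covars):
    """gamma, log-likelihood and summed two-slice statistics (for EM)."""
    n = pi.size
    if not np.allclose(A.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("transition matrix rows must sum to 1")
    logB = _log_mvn_density(X, means, covars)
    T = X.shape[0]
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    alpha = np.empty((T, n))
    c = np.empty(T)
    a = pi * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    loglik = float(np.log(c).sum() + shift.sum())
    beta = np.empty((T, n))
    beta[-1] = 1.0
    xi_sum = np.zeros((n, n))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = (A @ bb) / c[t + 1]
        xi_sum += np.outer(alpha[t], bb / c[t + 1]) * A
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, loglik, xi_sum


def hard_assign(gamma) -> np.ndarray:
    """Argmax state per timepoint; ties resolve to the lowest index."""
    gamma = check_matrix(gamma, "gamma")
    return np.argmax(gamma, axis=1)


class GaussianHMMStates(BaseEstimator):
    """Full-covariance Gaussian HMM fitted by Baum-Welch EM.

    Initialization seeds the state means at randomly chosen timepoints,
    shares the sample covariance across states, and biases the transition
    matrix toward persistence (0.8 self-transition mass).  Covariances are
    floored at ``reg * mean diagonal variance`` times the identity.

    Parameters
    ----------
    n_states : number of hidden states (study default 4).
    max_iter : EM iteration cap (study default 500).
    tol : relative log-likelihood change for convergence.
    reg : covariance floor scale.
    random_state : initialization seed.
    """

    def __init__(self, n_states=4, max_iter=500, tol=1e-4, reg=1e-6, random_state=0):
        self.n_states = n_states
        self.max_iter = max_iter
        self.tol = tol
        self.reg = reg
        self.random_state = random_state

    def _floor(self, X: np.ndarray) -> float:
        mean_var = float(np.mean(np.var(X, axis=0)))
        base = mean_var if mean_var > 0 else 1.0
        return max(self.reg * base, 1e-12)

    def fit(self, X, y=None):
        X = check_matrix(X, "series")
        T, R = X.shape
        n = int(self.n_states)
        if T <= n:
            raise ValueError(f"need more than {n} timepoints, got {T}")
        rng = np.random.default_rng(self.random_state)
        floor = self._floor(X)
        idx = rng.choice(T, size=n, replace=False)
        means = X[idx].copy()
        base_cov = np.cov(X, rowvar=False).reshape(R, R) + floor * np.eye(R)
        covars = np.repeat(base_cov[None], n, axis=0)
        pi = np.full(n, 1.0 / n)
        A = 0.8 * np.eye(n) + 0.2 / n
        if np.allclose(X.std(axis=0), 0.0):
            warnings.warn("input series is constant; EM will degenerate")
        trace: list[float] = []
        converged = False
        gamma = np.full((T, n), 1.0 / n)
        for it in range(int(self.max_iter)):
            gamma, loglik, xi_sum = _forward_backward_full(X, pi, A, means, covars)
            if trace and loglik < trace[-1] - 1e-8 * max(1.0, abs(trace[-1])):
                logger.warning("EM log-likelihood decreased at iteration %d", it)
            if trace and abs(loglik - trace[-1]) <= self.tol * max(
                abs(trace[-1]), 1e-12
            ):
                trace.append(loglik)
                converged = True
                break
            trace.append(loglik)
            # M-step
            Ng = gamma.sum(axis=0)
            Ng_safe = np.where(Ng > 0, Ng, 1.0)
            pi = np.clip(gamma[0], 1e-12, None)
            pi /= pi.sum()
            row = xi_sum.sum(axis=1, keepdims=True)
            A = np.where(row > 0, xi_sum / np.where(row == 0, 1.0, row), 1.0 / n)
            A = np.clip(A, 1e-12, None)
            A /= A.sum(axis=1, keepdims=True)
            means = (gamma.T @ X) / Ng_safe[:, None]
            for k in range(n):
                diff = X - means[k]
                covars[k] = (diff.T * gamma[:, k]) @ diff / Ng_safe[k]
                covars[k] += floor * np.eye(R)
                covars[k] = 0.5 * (covars[k] + covars[k].T)
        else:
            # ran to the cap: refresh posteriors for the final parameters
            gamma, loglik, _ = _forward_backward_full(X, pi, A, means, covars)
            if not trace or loglik >= trace[-1]:
                trace.append(loglik)
        self.startprob_ = pi
        self.transmat_ = A
        self.means_ = means
        self.covars_ = covars
        self.gamma_ = gamma
        self.log_likelihood_ = trace[-1]
        self.loglik_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = len(trace)
        self.n_features_in_ = R
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "means_")
        gamma, _ = forward_backward(
            X, self.startprob_, self.transmat_, self.means_, self.covars_
        )
        return gamma

    def predict(self, X):
        return hard_assign(self.predict_proba(X))

    def score(self, X, y=None):
        check_is_fitted(self, "means_")
        _, loglik = forward_backward(
            X, self.startprob_, self.transmat_, self.means_, self.covars_
        )
        return loglik

    def to_solution(self, seed=None) -> HMMSolution:
        check_is_fitted(self, "means_")
        return HMMSolution(
            n=int(self.n_states),
            startprob=self.startprob_.copy(),
            transmat=self.transmat_.copy(),
            means=self.means_.copy(),
            covars=self.covars_.copy(),
            gamma=self.gamma_.copy(),
            log_likelihood=self.log_likelihood_,
            seed=seed,
            n_iter=self.n_iter_,
            converged=self.converged_,
            loglik_trace=list(self.loglik_trace_),
        )


def fit_hmm_em(
    series,
    n_states: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> HMMSolution:
    """Single EM fit from one seeded initialization."""
    est = GaussianHMMStates(
        n_states=n_states, max_iter=max_iter, tol=tol, random_state=seed
    )
    est.fit(series)
    return est.to_solution(seed=seed)


def multi_restart_fit(
    series,
    n_states: int,
    contexts_W,
    n_restarts: int = 100,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    k: int = 10,
    absolute: bool = False,
) -> HMMSolution:
    """Restart EM ``n_restarts`` times; keep the semantically strongest fit.

    Each restart's model-level link index is the mean over states of the
    state's top-k mean Pearson correlation with the semantic-context
    expressions ``contexts_W``; ``absolute=True`` ranks |r| instead of
    signed r.  All restart indices are logged on the returned solution.
    """
    from .linkage import correlation_matrix, top_k_link_strength

    contexts_W = check_matrix(contexts_W, "contexts_W")
    series = check_matrix(series, "series")
    if contexts_W.shape[0] != series.shape[0]:
        raise ValueError("contexts_W must have one row per timepoint")
    seeds = spawn_seeds(seed, int(n_restarts))
    best: HMMSolution | None = None
    indices: list[float] = []
    for s in seeds:
        sol = fit_hmm_em(series, n_states, seed=s, max_iter=max_iter, tol=tol)
        P = correlation_matrix(sol.gamma, contexts_W)
        if absolute:
            P = np.abs(P)
        _, index = top_k_link_strength(P, k=k)
        sol.link_index = index
        indices.append(index)
        if best is None or index > best.link_index:
            best = sol
    assert best is not None
    best.restart_link_indices = indices
    return best


def bic(solution: HMMSolution, T: int) -> float:
    """Bayesian information criterion of a fitted solution.

    Free parameters: (n-1) initial probabilities, n(n-1) transition entries,
    and per state R mean + R(R+1)/2 covariance entries.
    """
    n, R = solution.n, solution.R
    p = (n - 1) + n * (n - 1) + n * (R + R * (R + 1) // 2)
    return float(-2.0 * solution.log_likelihood + p * np.log(T))


def _align_gammas(ref_sol: HMMSolution, other_sol: HMMSolution) -> np.ndarray:
    from .grouplevel import align_states

    mapping = align_states(ref_sol, other_sol).permutation
    aligned = np.empty_like(other_sol.gamma)
    for src, dst in enumerate(mapping):
        aligned[:, dst] = other_sol.gamma[:, src]
    return aligned


def select_n_states(
    series,
    contexts_W,
    candidate_range=range(2, 9),
    n_restarts: int = 5,
    seed: int = 0,
    limbic_columns=None,
    max_iter: int = 500,
    tol: float = 1e-4,
):
    """Sweep candidate state counts and score each on four criteria.

    ``series`` is a single T x R matrix or a list of per-subject matrices.
    The table reports, per candidate n: mean top-10 link index, mean
    cross-subject state-presence similarity (NaN with one subject), BIC on
    the full feature set, and BIC with the limbic columns removed (NaN when
    ``limbic_columns`` is None).  Selection = argmin full-feature BIC, ties
    broken by the larger link index.  Returns ``(selected_n, table)``.
    """
    candidates = list(candidate_range)
    if not candidates:
        raise ValueError("candidate_range is empty")
    subjects = series if isinstance(series, (list, tuple)) else [series]
    subjects = [check_matrix(s, "series") for s in subjects]
    rows = []
    for n in candidates:
        sols = []
        for i, X in enumerate(subjects):
            sols.append(
                multi_restart_fit(
                    X,
                    n,
                    contexts_W,
                    n_restarts=n_restarts,
                    seed=seed + 1000 * i,
                    max_iter=max_iter,
                    tol=tol,
                )
            )
        link = float(np.mean([s.link_index for s in sols]))
        bic_full = float(np.mean([bic(s, X.shape[0]) for s, X in zip(sols, subjects)]))
        if len(subjects) > 1:
            aligned = [sols[0].gamma] + [_align_gammas(sols[0], s) for s in sols[1:]]
            sims = []
            for a, b in itertools.combinations(aligned, 2):
                sims.extend(
                    np.corrcoef(a[:, j], b[:, j])[0, 1] for j in range(n)
                )
            similarity = float(np.nanmean(sims))
        else:
            similarity = float("nan")
        if limbic_columns is not None:
            keep = [
                j for j in range(subjects[0].shape[1]) if j not in set(limbic_columns)
            ]
            bics = []
            for i, X in enumerate(subjects):
                sol = multi_restart_fit(
                    X[:, keep],
                    n,
                    contexts_W,
                    n_restarts=n_restarts,
                    seed=seed + 1000 * i + 500,
                    max_iter=max_iter,
                    tol=tol,
                )
                bics.append(bic(sol, X.shape[0]))
            bic_nolimbic = float(np.mean(bics))
        else:
            bic_nolimbic = float("nan")
        rows.append(
            {
                "n_states": n,
                "mean_top10_link": link,
                "cross_subject_similarity": similarity,
                "bic": bic_full,
                "bic_no_limbic": bic_nolimbic,
            }
        )
    table = pd.DataFrame(rows)
    best_bic = table["bic"].min()
    tied = table[np.isclose(table["bic"], best_bic)]
    selected = int(tied.loc[tied["mean_top10_link"].idxmax(), "n_states"])
    return selected, table
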