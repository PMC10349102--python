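"""Semantics-brain and annotation-brain association statistics.

Pearson correlation matrices between state-presence trajectories and
external feature trajectories (semantic-context expressions W, annotation
IOA series), the per-state top-k link strength and its model-level mean,
permutation nulls obtained by jointly shuffling the state-presence rows,
and two-sample network comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import check_matrix

logger = logging.getLogger(__name__)


@dataclass
class LinkageProfile:
    """Association summary for one fitted model."""

    P_semantic: np.ndarray  # (s, n)
    per_state_top_k: list[list[tuple[int, float]]]
    per_state_top_k_mean: np.ndarray
    model_link_index: float
    P_annotation: np.ndarray | None = None
    permutation_p: float | None = None
    null_sample: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def _standardize_columns(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores (population sd); flags zero-variance columns."""
    mean = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    degenerate = sd[0] == 0
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mean) / sd, degenerate


def correlation_matrix(gamma: np.ndarray, features: np.ndarray) -> np.ndarray:
    """Pearson r between every feature column and every state column.

    Returns an (F, n) matrix.  Zero-variance columns on either side yield
    r = 0 by convention, with a logged warning.
    """
    gamma = check_matrix(gamma, "gamma")
    features = check_matrix(features, "features")
    if gamma.shape[0] != features.shape[0]:
        raise ValueError(
            f"row mismatch: gamma has {gamma.shape[0]} rows, "
            f"features has {features.shape[0]}"
        )
    zg, deg_g = _standardize_columns(gamma)
    zf, deg_f = _standardize_columns(features)
    if deg_g.any() or deg_f.any():
        logger.warning(
            "constant columns in correlation_matrix (%d states, %d features); "
            "their correlations are set to 0",
            int(deg_g.sum()),
            int(deg_f.sum()),
        )
    P = zf.T @ zg / gamma.shape[0]
    P[deg_f, :] = 0.0
    P[:, deg_g] = 0.0
    return np.clip(P, -1.0, 1.0)


def top_k_link_strength(P: np.ndarray, k: int = 10):
    """Mean of each state's k largest signed correlations, and their mean.

    Returns ``(per_state_means, model_index)``.  If fewer than k features are
    available, all are used (with a warning).
    """
    P = check_matrix(P, "P")
    F = P.shape[0]
    if F < 1:
        raise ValueError("P must have at least one feature row")
    kk = int(k)
    if F < kk:
        logger.warning("only %d features available for top-%d statistic", F, kk)
        kk = F
    top = -np.sort(-P, axis=0)[:kk]
    per_state = top.mean(axis=0)
    return per_state, float(per_state.mean())


def top_k_links(P: np.ndarray, k: int = 10) -> list[list[tuple[int, float]]]:
    """Per state: the k strongest (feature_index, r) pairs, descending."""
    P = check_matrix(P, "P")
    kk = min(int(k), P.shape[0])
    out = []
    for j in range(P.shape[1]):
        order = np.argsort(-P[:, j], kind="stable")[:kk]
        out.append([(int(i), float(P[i, j])) for i in order])
    return out


def permutation_test(
    gamma: np.ndarray,
    features: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    k: int = 10,
    circular: bool = False,
):
    """Permutation null for the model-level top-k link index.

    Each of B draws applies one random row permutation jointly to all gamma
    columns (preserving the per-row simplex) and recomputes the index;
    ``circular=True`` uses random circular shifts instead, preserving
    temporal autocorrelation.  p = (1 + #{null >= observed}) / (1 + B).
    """
    gamma = check_matrix(gamma, "gamma")
    features = check_matrix(features, "features")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    T = gamma.shape[0]
    _, observed = top_k_link_strength(correlation_matrix(gamma, features), k=k)
    # precompute standardized features once; correlations are then one matmul
    zf, deg_f = _standardize_columns(features)
    zf = zf.copy()
    zf[:, deg_f] = 0.0
    zg, deg_g = _standardize_columns(gamma)
    zg = zg.copy()
    zg[:, deg_g] = 0.0
    null = np.empty(B)
    for b in range(B):
        if circular:
            shift = int(rng.integers(1, T))
            zperm = np.roll(zg, shift, axis=0)
        else:
            zperm = zg[rng.permutation(T)]
        P = zf.T @ zperm / T
        _, null[b] = top_k_link_strength(P, k=k)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + B)
    return float(observed), null, float(p)


def compare_networks(
    link_table: pd.DataFrame,
    reference: str,
    equal_var: bool = True,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Two-sample t-tests of the reference network's per-subject link
    indices against each other network's.

    ``link_table`` is subjects x networks.  Returns one row per non-reference
    network with t and p (optionally Bonferroni-scaled).
    """
    if reference not in link_table.columns:
        raise KeyError(f"reference network {reference!r} not in table")
    if len(link_table) < 2:
        raise ValueError("need at least 2 subjects per network")
    ref = link_table[reference].to_numpy(dtype=float)
    rows = []
    others = [c for c in link_table.columns if c != reference]
    for col in others:
        t, p = stats.ttest_ind(
            ref, link_table[col].to_numpy(dtype=float), equal_var=equal_var
        )
        if bonferroni:
            p = min(1.0, p * len(others))
        rows.append({"network": col, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def linkage_profile(
    gamma: np.ndarray,
    contexts_W: np.ndarray,
    annotations: np.ndarray | None = None,
    k: int = 10,
    B: int = 0,
    seed: int = 0,
) -> LinkageProfile:
    """Full association summary for one model (optionally with a null)."""
    P_sem = correlation_matrix(gamma, contexts_W)
    per_state, model_index = top_k_link_strength(P_sem, k=k)
    profile = LinkageProfile(
        P_semantic=P_sem,
        per_state_top_k=top_k_links(P_sem, k=k),
        per_state_top_k_mean=per_state,
        model_link_index=model_index,
    )
    if annotations is not None:
        profile.P_annotation = correlation_matrix(gamma, annotations)
    if B:
        _, null, p = permutation_test(gamma, contexts_W, B=B, seed=seed, k=k)
        profile.null_sample = null
        profile.permutation_p = p
    return profile
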