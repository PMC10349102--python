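"""Signal preparation: per-segment standardization, shared-hemisphere PCA
embedding of limbic subregions, and region-network feature assembly.

Each region-network combination pairs one neocortical network's parcel
series (r_network columns, 5..24 in the reference atlas) with 3 principal
components per hemisphere of one limbic structure (hippocampus or
amygdala), for a total feature count R = r_network + 2 * r_limbic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from ._utils import check_matrix, check_partition


@dataclass
class CombinationSeries:
    """T x R feature matrix for one subject and one region-network combination."""

    subject_id: object
    network: str
    limbic_structure: str  # "HC" or "AM"
    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = check_matrix(self.values, "values")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("label count does not match column count")

    @property
    def R(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.labels)


class SegmentStandardizer(TransformerMixin, BaseEstimator):
    """Per-segment linear detrend + z-score, column by column.

    Within each movie segment and each column, the least-squares line is
    removed and the residual is scaled to mean 0 / sd 1 (population sd).
    Columns constant within a segment become zeros.  Idempotent.
    """

    def __init__(self, segment_bounds=None):
        self.segment_bounds = segment_bounds

    def fit(self, X, y=None):
        X = check_matrix(X)
        bounds = self.segment_bounds or [(0, X.shape[0])]
        self.bounds_ = check_partition(bounds, X.shape[0])
        return self

    def transform(self, X):
        check_is_fitted(self, "bounds_")
        X = check_matrix(X)
        out = np.empty_like(X)
        for a, b in self.bounds_:
            seg = X[a:b]
            t = np.arange(b - a, dtype=float)
            t -= t.mean()
            denom = (t**2).sum()
            if denom > 0:
                slope = (t[:, None] * (seg - seg.mean(axis=0))).sum(axis=0) / denom
                resid = seg - seg.mean(axis=0) - t[:, None] * slope
            else:  # single-timepoint segment
                resid = seg - seg.mean(axis=0)
            sd = resid.std(axis=0)
            sd_safe = np.where(sd == 0, 1.0, sd)
            out[a:b] = np.where(sd == 0, 0.0, resid / sd_safe)
        return out


def segmentwise_standardize(series, segment_bounds) -> np.ndarray:
    """Functional wrapper over :class:`SegmentStandardizer`."""
    return SegmentStandardizer(segment_bounds).fit(series).transform(series)


class SharedHemisphericPCAError(ValueError):
    pass


class SharedHemispherePCA(TransformerMixin, BaseEstimator):
    """One PCA model shared by both hemispheres of a limbic structure.

    The two hemispheres' subregion series (each T x m) are centered per
    hemisphere, row-stacked along the time axis (2T x m), and a single set
    of components is fitted; each hemisphere is then projected with that
    shared basis, allowing lateralization to express itself in the scores.
    Component signs are fixed by making each component's largest-magnitude
    element positive.

    Attributes
    ----------
    components_ : (n_components, m) shared orthonormal basis.
    mean_left_, mean_right_ : per-hemisphere column means.
    explained_variance_ratio_ : fractions of stacked variance, nonincreasing.
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, left, right=None):
        left = check_matrix(left, "left")
        right = check_matrix(right, "right")
        if left.shape != right.shape:
            raise SharedHemisphericPCAError(
                f"hemisphere shapes differ: {left.shape} vs {right.shape}"
            )
        m = left.shape[1]
        if self.n_components > m:
            raise SharedHemisphericPCAError(
                f"n_components={self.n_components} exceeds {m} subregions"
            )
        self.mean_left_ = left.mean(axis=0)
        self.mean_right_ = right.mean(axis=0)
        stacked = np.vstack([left - self.mean_left_, right - self.mean_right_])
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(stacked)
        comps = pca.components_
        # deterministic sign: largest-|entry| element positive
        for i in range(comps.shape[0]):
            j = int(np.argmax(np.abs(comps[i])))
            if comps[i, j] < 0:
                comps[i] = -comps[i]
        self.components_ = comps
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        return self

    def transform(self, left, right=None):
        """Project both hemispheres; columns ordered L-PC1..k then R-PC1..k."""
        check_is_fitted(self, "components_")
        left = check_matrix(left, "left")
        right = check_matrix(right, "right")
        zl = (left - self.mean_left_) @ self.components_.T
        zr = (right - self.mean_right_) @ self.components_.T
        return np.hstack([zl, zr])

    def fit_transform(self, left, right=None):
        return self.fit(left, right).transform(left, right)

    def inverse_transform_loadings(self, pc_loadings) -> np.ndarray:
        """Map a length-2k PC-space loading vector back to 2m subregions.

        The left-hemisphere block comes first in both spaces.
        """
        check_is_fitted(self, "components_")
        v = np.asarray(pc_loadings, dtype=float).ravel()
        k = self.components_.shape[0]
        if v.size != 2 * k:
            raise SharedHemisphericPCAError(
                f"expected {2 * k} PC loadings, got {v.size}"
            )
        return np.concatenate(
            [self.components_.T @ v[:k], self.components_.T @ v[k:]]
        )


def fit_limbic_pca(left, right, n_pc: int = 3):
    """Fit the shared-hemisphere PCA; returns (model, T x 2*n_pc embeddings)."""
    model = SharedHemispherePCA(n_components=n_pc)
    emb = model.fit_transform(left, right)
    return model, emb


def inverse_project_loadings(model: SharedHemispherePCA, pc_loadings) -> np.ndarray:
    return model.inverse_transform_loadings(pc_loadings)


def assemble_combination(
    network_series,
    limbic_embeddings,
    labels: list[str],
    subject_id=None,
    network: str = "",
    limbic_structure: str = "",
) -> CombinationSeries:
    """Column-concatenate network parcels with limbic PC embeddings."""
    network_series = check_matrix(network_series, "network_series")
    limbic_embeddings = check_matrix(limbic_embeddings, "limbic_embeddings")
    if network_series.shape[0] != limbic_embeddings.shape[0]:
        raise ValueError(
            f"row mismatch: {network_series.shape[0]} vs {limbic_embeddings.shape[0]}"
        )
    values = np.hstack([network_series, limbic_embeddings])
    return CombinationSeries(
        subject_id=subject_id,
        network=network,
        limbic_structure=limbic_structure,
        values=values,
        labels=list(labels),
    )
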