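"""Individual regional radiomics similarity networks (R2SN).

A subject's network has one node per atlas region; the edge between two
regions is the Pearson correlation of their (normalized, redundancy-pruned)
radiomics feature vectors.  The construction order is: min-max normalize
each feature across regions within the subject, prune mutually redundant
features (|r| above a threshold on a reference cohort), then correlate
region pairs over the retained features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateFeatureError, DegenerateRegionError, ParameterError
from .features import RegionalFeatureMatrix

__all__ = [
    "R2SNMatrix",
    "EdgeVector",
    "FeatureRetention",
    "minmax_normalize",
    "fit_feature_retention",
    "build_r2sn",
    "vectorize_edges",
    "devectorize_edges",
    "edge_index",
    "edge_ids",
]


@dataclass
class R2SNMatrix:
    """Symmetric region x region correlation network of one subject."""

    subject_id: str
    matrix: np.ndarray
    region_ids: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.region_ids = list(self.region_ids)
        n = len(self.region_ids)
        if self.matrix.shape != (n, n):
            raise ParameterError("network matrix is not square over region_ids")

    def validate(self):
        m = self.matrix
        if not np.allclose(m, m.T):
            raise ParameterError("network is not symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ParameterError("network diagonal is not 1")
        if m.min() < -1 - 1e-12 or m.max() > 1 + 1e-12:
            raise ParameterError("edges outside [-1, 1]")
        return self


@dataclass
class EdgeVector:
    """Canonical upper-triangle flattening of a network (row-major, i<j)."""

    subject_id: str
    values: np.ndarray
    region_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.region_ids)
        if self.values.shape != (n * (n - 1) // 2,):
            raise ParameterError("edge vector length does not match region count")


@dataclass
class FeatureRetention:
    """Frozen list of non-redundant features fitted on a reference cohort."""

    retained: list
    threshold: float = 0.9
    provenance: str = ""

    def __post_init__(self):
        if not self.retained:
            raise ParameterError("retained feature list is empty")


def edge_index(n: int):
    """Canonical ordered (i, j) index pairs, i<j, row-major upper triangle."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def edge_ids(region_ids) -> list:
    """Canonical edge identifiers "<region_i>_<region_j>"."""
    rid = list(region_ids)
    return [f"{rid[i]}_{rid[j]}" for i, j in edge_index(len(rid))]


def minmax_normalize(fm: RegionalFeatureMatrix) -> RegionalFeatureMatrix:
    """Map each feature column to [0, 1] across the subject's regions.

    Raises :class:`DegenerateFeatureError` naming the first constant column.
    """
    m = fm.matrix
    if m.shape[0] < 2:
        raise ParameterError("min-max normalization needs at least 2 regions")
    lo = m.min(axis=0)
    hi = m.max(axis=0)
    span = hi - lo
    bad = np.nonzero(span == 0)[0]
    if bad.size:
        raise DegenerateFeatureError(
            f"constant feature column(s): {[fm.feature_names[i] for i in bad]}"
        )
    out = fm.copy()
    out.matrix = (m - lo) / span
    return out


def fit_feature_retention(
    fms, threshold: float = 0.9, provenance: str = ""
) -> FeatureRetention:
    """Greedy redundancy pruning of features on a pooled reference cohort.

    Feature-feature Pearson correlations are computed on region rows pooled
    across all given (normalized) subjects.  Scanning features in canonical
    order, a feature is dropped iff its |r| with an already-retained feature
    exceeds ``threshold``; the scan is deterministic.
    """
    fms = list(fms)
    if not fms:
        raise ParameterError("need at least one subject to fit retention")
    names = fms[0].feature_names
    for fm in fms:
        if fm.feature_names != names:
            raise ParameterError("subjects disagree on feature names")
    pooled = np.vstack([fm.matrix for fm in fms])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(pooled, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # constant pooled column: not redundant
    retained_idx: list[int] = []
    for f in range(len(names)):
        if all(abs(corr[f, r]) <= threshold for r in retained_idx):
            retained_idx.append(f)
    if not retained_idx:  # unreachable with the rule above, kept for clarity
        retained_idx = [0]
    return FeatureRetention(
        retained=[names[i] for i in retained_idx],
        threshold=threshold,
        provenance=provenance,
    )


def build_r2sn(fm: RegionalFeatureMatrix, retention: FeatureRetention) -> R2SNMatrix:
    """Correlate every region pair over the retained features."""
    missing = [f for f in retention.retained if f not in fm.feature_names]
    if missing:
        raise ParameterError(f"retained features absent from subject: {missing}")
    if len(retention.retained) < 2:
        raise ParameterError("need at least 2 retained features to correlate regions")
    cols = [fm.feature_names.index(f) for f in retention.retained]
    sub = fm.matrix[:, cols]
    sd = sub.std(axis=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise DegenerateRegionError(
            f"zero-variance region(s) across retained features: "
            f"{[fm.region_ids[i] for i in bad]}"
        )
    net = np.corrcoef(sub)
    net = np.clip(net, -1.0, 1.0)
    np.fill_diagonal(net, 1.0)
    net = (net + net.T) / 2.0
    return R2SNMatrix(subject_id=fm.subject_id, matrix=net, region_ids=fm.region_ids)


def vectorize_edges(net: R2SNMatrix) -> EdgeVector:
    """Flatten the upper triangle in canonical order."""
    n = len(net.region_ids)
    iu = np.triu_indices(n, k=1)
    return EdgeVector(
        subject_id=net.subject_id, values=net.matrix[iu], region_ids=net.region_ids
    )


def devectorize_edges(ev: EdgeVector) -> R2SNMatrix:
    """Inverse of :func:`vectorize_edges` (unit diagonal restored)."""
    n = len(ev.region_ids)
    if ev.values.shape[0] != n * (n - 1) // 2:
        raise ParameterError("edge vector length does not match region count")
    m = np.eye(n)
    iu = np.triu_indices(n, k=1)
    m[iu] = ev.values
    m[(iu[1], iu[0])] = ev.values
    return R2SNMatrix(subject_id=ev.subject_id, matrix=m, region_ids=ev.region_ids)
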