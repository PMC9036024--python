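"""MCI subtyping by rank-2 nonnegative matrix factorization.

Subjects' consistent-connection profiles (mapped from [-1, 1] to [0, 1])
are factorized into two nonnegative components; each subject's larger
coefficient defines a hard cluster, and the coefficient ratio gives the
probability of belonging to the AD-like cluster.  Components are labeled
A-CI / N-CI by the distance of their member-weighted mean profile to the
AD and NC group mean profiles.  Cross-parcellation reproducibility is
quantified by a symmetrized overlap AUC and by the correlation of the
A-like probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .exceptions import DegenerateInputError, ParameterError

__all__ = [
    "SubtypeAssignment",
    "to_nonnegative",
    "from_nonnegative",
    "nmf",
    "nmf_cluster",
    "label_components",
    "clustering_overlap_auc",
    "probability_correlation",
]

A_CI = "A-CI"
N_CI = "N-CI"


@dataclass
class SubtypeAssignment:
    subject_ids: list
    coefficients: np.ndarray  # subjects x 2, nonnegative
    reconstruction_error: float
    seed: int
    n_restarts: int
    labels: np.ndarray = field(default=None)  # A-CI / N-CI after labeling
    p_adlike: np.ndarray = field(default=None)
    adlike_component: int = -1
    error_trace: np.ndarray = field(default=None)


def to_nonnegative(x: np.ndarray) -> np.ndarray:
    """Affine map [-1, 1] -> [0, 1]: x -> (x + 1) / 2 (order-preserving)."""
    x = np.asarray(x, dtype=float)
    if np.nanmin(x) < -1 - 1e-12 or np.nanmax(x) > 1 + 1e-12:
        raise ParameterError("values outside [-1, 1]")
    return (x + 1.0) / 2.0


def from_nonnegative(y: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_nonnegative`."""
    y = np.asarray(y, dtype=float)
    if np.nanmin(y) < -1e-12 or np.nanmax(y) > 1 + 1e-12:
        raise ParameterError("values outside [0, 1]")
    return 2.0 * y - 1.0


def nmf(
    X: np.ndarray,
    rank: int = 2,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
):
    """Frobenius NMF by multiplicative updates, best of ``n_restarts``.

    Returns (W, H, error, trace): W is subjects x rank, H rank x edges,
    error the Frobenius reconstruction error of the best restart, trace its
    per-iteration error sequence (non-increasing up to floating point).
    """
    X = np.asarray(X, dtype=float)
    if X.min() < 0:
        raise ParameterError("NMF input must be nonnegative")
    if not X.any():
        raise DegenerateInputError("all-zero matrix cannot be factorized")
    eps = 1e-12
    best = None
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        # H is random; W is seeded from X rows so that permuting subjects
        # permutes the factorization (and its error) identically
        scale = np.sqrt(X.mean() / rank)
        H = rng.uniform(eps, 1.0, (rank, X.shape[1])) * scale
        W = X @ H.T / max(float((H * H).sum()), eps) + eps
        trace = []
        prev = np.inf
        for _ in range(max_iter):
            H *= (W.T @ X) / (W.T @ W @ H + eps)
            W *= (X @ H.T) / (W @ H @ H.T + eps)
            err = float(np.linalg.norm(X - W @ H))
            trace.append(err)
            if prev - err < tol * max(prev, 1.0):
                break
            prev = err
        if best is None or trace[-1] < best[2]:
            best = (W, H, trace[-1], np.array(trace))
    return best


def nmf_cluster(
    profiles: np.ndarray,
    subject_ids=None,
    seed: int = 0,
    n_restarts: int = 20,
) -> SubtypeAssignment:
    """Rank-2 NMF of subject x consistent-edge nonnegative profiles."""
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ParameterError("need a 2D matrix with at least 2 subjects")
    if subject_ids is None:
        subject_ids = [str(i) for i in range(X.shape[0])]
    W, H, err, trace = nmf(X, rank=2, seed=seed, n_restarts=n_restarts)
    return SubtypeAssignment(
        subject_ids=list(subject_ids),
        coefficients=W,
        reconstruction_error=err,
        seed=seed,
        n_restarts=n_restarts,
        error_trace=trace,
    )


def label_components(
    assignment: SubtypeAssignment,
    mci_profiles: np.ndarray,
    nc_mean_profile: np.ndarray,
    ad_mean_profile: np.ndarray,
) -> SubtypeAssignment:
    """Name the components A-CI / N-CI by proximity to the AD mean profile.

    Each component's centroid is the coefficient-weighted mean of its
    members' profiles; the centroid closer (Euclidean) to the AD mean
    profile is A-CI.  An exact distance tie raises ParameterError.
    """
    X = np.asarray(mci_profiles, dtype=float)
    W = assignment.coefficients
    if X.shape[0] != W.shape[0]:
        raise ParameterError("profiles and coefficients disagree on subjects")
    nc = np.asarray(nc_mean_profile, dtype=float)
    ad = np.asarray(ad_mean_profile, dtype=float)
    if nc.shape != (X.shape[1],) or ad.shape != (X.shape[1],):
        raise ParameterError("mean profiles must live in the consistent-edge space")
    d_ad = np.empty(2)
    for k in range(2):
        wk = W[:, k]
        if wk.sum() <= 0:
            raise DegenerateInputError(f"component {k} has zero total coefficient")
        centroid = (wk @ X) / wk.sum()
        d_ad[k] = np.linalg.norm(centroid - ad)
    if d_ad[0] == d_ad[1]:
        raise ParameterError("exact distance tie between components")
    a_comp = int(np.argmin(d_ad))
    total = W.sum(axis=1)
    p_adlike = np.where(total > 0, W[:, a_comp] / np.where(total > 0, total, 1.0), 0.5)
    hard = np.argmax(W, axis=1)
    labels = np.where(hard == a_comp, A_CI, N_CI)
    assignment.labels = labels
    assignment.p_adlike = p_adlike
    assignment.adlike_component = a_comp
    return assignment


def _overlap_auc_oneway(labels_ref: np.ndarray, p_other: np.ndarray) -> float:
    y = (np.asarray(labels_ref) == A_CI).astype(int)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("reference labels contain a single class")
    return float(roc_auc_score(y, np.asarray(p_other, dtype=float)))


def clustering_overlap_auc(a: SubtypeAssignment, b: SubtypeAssignment) -> float:
    """Symmetrized AUC of one run's A-like probability against the other's labels."""
    if a.subject_ids != b.subject_ids:
        raise ParameterError("assignments cover different subjects")
    if a.labels is None or b.labels is None or a.p_adlike is None or b.p_adlike is None:
        raise ParameterError("assignments must be labeled first")
    return 0.5 * (
        _overlap_auc_oneway(a.labels, b.p_adlike)
        + _overlap_auc_oneway(b.labels, a.p_adlike)
    )


def probability_correlation(a: SubtypeAssignment, b: SubtypeAssignment):
    """Pearson (r, p) between the two runs' A-like probabilities."""
    if a.subject_ids != b.subject_ids:
        raise ParameterError("assignments cover different subjects")
    if a.p_adlike is None or b.p_adlike is None:
        raise ParameterError("assignments must be labeled first")
    r, p = stats.pearsonr(a.p_adlike, b.p_adlike)
    return float(r), float(p)
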