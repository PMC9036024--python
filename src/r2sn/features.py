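"""Regional radiomics feature extraction.

Computes 47 quantitative descriptors per parcellation region of a 3D
intensity volume: 14 first-order statistics of the regional intensity
distribution, 22 gray-level co-occurrence matrix (GLCM) texture features,
and 11 gray-level run-length matrix (GLRLM) texture features.

Texture features follow the standard IBSI-style definitions.  Intensities
are discretized per region with a fixed bin count over the region's own
min-max range; GLCM/GLRLM features are computed per 3D direction (the 13
unique distance-1 neighbours) and averaged over directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptyRegionError, MissingRegionError, ParameterError

__all__ = [
    "FIRST_ORDER_FEATURES",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "CANONICAL_FEATURES",
    "DEFAULT_OFFSETS",
    "TextureMatrixConfig",
    "FeatureVector",
    "RegionalFeatureMatrix",
    "discretize",
    "cooccurrence_matrix",
    "run_length_matrix",
    "extract_region_features",
    "extract_subject_features",
]

FIRST_ORDER_FEATURES = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "range",
    "variance",
    "standard_deviation",
    "skewness",
    "kurtosis",
    "energy",
    "root_mean_square",
    "mean_absolute_deviation",
    "entropy",
    "uniformity",
)

GLCM_FEATURES = (
    "glcm_autocorrelation",
    "glcm_joint_average",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_cluster_tendency",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_difference_average",
    "glcm_difference_entropy",
    "glcm_difference_variance",
    "glcm_joint_energy",
    "glcm_joint_entropy",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_inverse_difference",
    "glcm_inverse_difference_normalized",
    "glcm_inverse_difference_moment",
    "glcm_inverse_difference_moment_normalized",
    "glcm_inverse_variance",
    "glcm_maximum_probability",
    "glcm_sum_entropy",
    "glcm_sum_of_squares",
)

GLRLM_FEATURES = (
    "glrlm_short_run_emphasis",
    "glrlm_long_run_emphasis",
    "glrlm_gray_level_nonuniformity",
    "glrlm_run_length_nonuniformity",
    "glrlm_run_percentage",
    "glrlm_low_gray_level_run_emphasis",
    "glrlm_high_gray_level_run_emphasis",
    "glrlm_short_run_low_gray_level_emphasis",
    "glrlm_short_run_high_gray_level_emphasis",
    "glrlm_long_run_low_gray_level_emphasis",
    "glrlm_long_run_high_gray_level_emphasis",
)

CANONICAL_FEATURES = FIRST_ORDER_FEATURES + GLCM_FEATURES + GLRLM_FEATURES

# 13 unique 3D directions at Chebyshev distance 1 (one of each +/- pair).
DEFAULT_OFFSETS = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


@dataclass(frozen=True)
class TextureMatrixConfig:
    """Configuration of the texture-matrix substrate.

    n_bins: fixed bin count for per-region min-max discretization.
    offsets: 3D displacement vectors; texture features are averaged over them.
    symmetric: count each voxel pair in both orders in the GLCM.
    normalization: convert GLCM counts to a joint probability mass.
    """

    n_bins: int = 32
    offsets: tuple = DEFAULT_OFFSETS
    symmetric: bool = True
    normalization: bool = True

    def __post_init__(self):
        if self.n_bins < 2:
            raise ParameterError("n_bins must be >= 2")
        if len(self.offsets) == 0:
            raise ParameterError("offsets must be nonempty")


@dataclass
class FeatureVector:
    """The 47 named features of one region."""

    region_id: int
    n_voxels: int
    values: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in CANONICAL_FEATURES])


@dataclass
class RegionalFeatureMatrix:
    """Per-subject regions x features table."""

    subject_id: str
    matrix: np.ndarray
    region_ids: list
    feature_names: list
    atlas_id: str = "synthetic"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.region_ids = list(self.region_ids)
        self.feature_names = list(self.feature_names)
        if self.matrix.shape != (len(self.region_ids), len(self.feature_names)):
            raise ParameterError("matrix shape does not match region/feature labels")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.matrix, index=self.region_ids, columns=self.feature_names
        )

    def copy(self) -> "RegionalFeatureMatrix":
        return RegionalFeatureMatrix(
            self.subject_id,
            self.matrix.copy(),
            list(self.region_ids),
            list(self.feature_names),
            self.atlas_id,
        )


# ---------------------------------------------------------------------------
# discretization and shifting primitives


def discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Fixed-bin-count discretization over the data's min-max range.

    Returns integer levels in 1..n_bins; a constant input maps to level 1.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.ones(x.shape, dtype=np.int64)
    levels = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    return np.clip(levels, 1, n_bins)


def _shift(a: np.ndarray, off, fill=0) -> np.ndarray:
    """out[x] = a[x + off], with `fill` outside the array."""
    out = np.full_like(a, fill)
    src, dst = [], []
    for n, o in zip(a.shape, off):
        if abs(o) >= n:
            return out
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = a[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# texture matrices


def cooccurrence_matrix(
    levels: np.ndarray,
    mask: np.ndarray,
    offset,
    n_bins: int,
    symmetric: bool = True,
    normalize: bool = False,
) -> np.ndarray:
    """GLCM: counts of co-occurring discretized levels at one offset.

    Only voxel pairs with both ends inside the mask contribute.  With
    ``symmetric`` each pair is counted in both orders; with ``normalize``
    the counts are divided by their total so the matrix is a joint
    probability mass (all zeros if no pair exists at this offset).
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    m2 = _shift(mask, offset, False)
    l2 = _shift(levels, offset, 0)
    pair = mask & m2
    P = np.zeros((n_bins, n_bins))
    if pair.any():
        np.add.at(P, (levels[pair] - 1, l2[pair] - 1), 1.0)
    if symmetric:
        P = P + P.T
    if normalize:
        total = P.sum()
        if total > 0:
            P = P / total
    return P


def run_length_matrix(
    levels: np.ndarray, mask: np.ndarray, direction, n_bins: int
) -> np.ndarray:
    """GLRLM: counts of maximal same-level runs along one direction.

    Entry (i, j) is the number of runs of discretized level i+1 with
    length j+1.  Runs are broken by the mask boundary or a level change.
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros((n_bins, 1))
    # same[x]: the run containues from x to x+direction
    same = mask & _shift(mask, direction, False) & (levels == _shift(levels, direction, -1))
    run_len = mask.astype(np.int64)
    while True:
        nxt = np.where(same, 1 + _shift(run_len, direction, 0), 1) * mask
        if np.array_equal(nxt, run_len):
            break
        run_len = nxt
    neg = tuple(-d for d in direction)
    start = mask & ~_shift(same, neg, False)
    gl = levels[start] - 1
    rl = run_len[start] - 1
    R = np.zeros((n_bins, int(rl.max()) + 1))
    np.add.at(R, (gl, rl), 1.0)
    return R


# ---------------------------------------------------------------------------
# feature formulas


def _first_order(x: np.ndarray, n_bins: int) -> dict:
    x = np.asarray(x, dtype=float)
    n = x.size
    mean = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    centered = x - mean
    if sd > 0:
        m3 = (centered**3).mean()
        m4 = (centered**4).mean()
        skew = m3 / sd**3
        kurt = m4 / var**2  # Pearson kurtosis (normal -> 3)
    else:
        skew = 0.0
        kurt = 0.0
    levels = discretize(x, n_bins)
    counts = np.bincount(levels, minlength=n_bins + 1)[1:]
    p = counts[counts > 0] / n
    return {
        "mean": mean,
        "median": float(np.median(x)),
        "minimum": x.min(),
        "maximum": x.max(),
        "range": x.max() - x.min(),
        "variance": var,
        "standard_deviation": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": (x**2).sum(),
        "root_mean_square": np.sqrt((x**2).mean()),
        "mean_absolute_deviation": np.abs(centered).mean(),
        "entropy": -(p * np.log2(p)).sum() if p.size else 0.0,
        "uniformity": (p**2).sum(),
    }


def _glcm_features(P: np.ndarray) -> dict:
    """All 22 GLCM features from a (symmetric) count or probability matrix."""
    n = P.shape[0]
    total = P.sum()
    if total == 0:
        return {k: 0.0 for k in GLCM_FEATURES}
    p = P / total
    iv = np.arange(1, n + 1, dtype=float)
    I, J = np.meshgrid(iv, iv, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = (iv * px).sum()
    uy = (iv * py).sum()
    sx = np.sqrt(((iv - ux) ** 2 * px).sum())
    sy = np.sqrt(((iv - uy) ** 2 * py).sum())

    # sum (k = 2..2n) and difference (k = 0..n-1) distributions
    p_sum = np.zeros(2 * n + 1)
    np.add.at(p_sum, (I + J).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(I - J).astype(int).ravel(), p.ravel())
    ks = np.arange(2 * n + 1, dtype=float)
    kd = np.arange(n, dtype=float)

    def _ent(q):
        q = q[q > 0]
        return -(q * np.log2(q)).sum() if q.size else 0.0

    diff_avg = (kd * p_diff).sum()
    pos = p > 0
    hxy = _ent(p)
    hx = _ent(px)
    hy = _ent(py)
    pxpy = np.outer(px, py)
    hxy1 = -(p[pos] * np.log2(pxpy[pos])).sum() if pos.any() else 0.0
    pospp = pxpy > 0
    hxy2 = -(pxpy[pospp] * np.log2(pxpy[pospp])).sum() if pospp.any() else 0.0
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    if sx * sy > 0:
        correlation = ((I * J * p).sum() - ux * uy) / (sx * sy)
    else:
        correlation = 1.0
    offdiag = I != J
    inv_var = (p[offdiag] / (I[offdiag] - J[offdiag]) ** 2).sum()
    return {
        "glcm_autocorrelation": (I * J * p).sum(),
        "glcm_joint_average": ux,
        "glcm_cluster_prominence": (((I + J - ux - uy) ** 4) * p).sum(),
        "glcm_cluster_shade": (((I + J - ux - uy) ** 3) * p).sum(),
        "glcm_cluster_tendency": (((I + J - ux - uy) ** 2) * p).sum(),
        "glcm_contrast": (((I - J) ** 2) * p).sum(),
        "glcm_correlation": correlation,
        "glcm_difference_average": diff_avg,
        "glcm_difference_entropy": _ent(p_diff),
        "glcm_difference_variance": (((kd - diff_avg) ** 2) * p_diff).sum(),
        "glcm_joint_energy": (p**2).sum(),
        "glcm_joint_entropy": hxy,
        "glcm_imc1": imc1,
        "glcm_imc2": imc2,
        "glcm_inverse_difference": (p / (1.0 + np.abs(I - J))).sum(),
        "glcm_inverse_difference_normalized": (p / (1.0 + np.abs(I - J) / n)).sum(),
        "glcm_inverse_difference_moment": (p / (1.0 + (I - J) ** 2)).sum(),
        "glcm_inverse_difference_moment_normalized": (
            p / (1.0 + (I - J) ** 2 / n**2)
        ).sum(),
        "glcm_inverse_variance": inv_var,
        "glcm_maximum_probability": p.max(),
        "glcm_sum_entropy": _ent(p_sum),
        "glcm_sum_of_squares": (((I - ux) ** 2) * p).sum(),
    }


def _glrlm_features(R: np.ndarray, n_voxels: int) -> dict:
    """All 11 GLRLM features from a run-count matrix (levels x lengths)."""
    nr = R.sum()
    if nr == 0:
        return {k: 0.0 for k in GLRLM_FEATURES}
    ng, nl = R.shape
    iv = np.arange(1, ng + 1, dtype=float)[:, None]
    jv = np.arange(1, nl + 1, dtype=float)[None, :]
    return {
        "glrlm_short_run_emphasis": (R / jv**2).sum() / nr,
        "glrlm_long_run_emphasis": (R * jv**2).sum() / nr,
        "glrlm_gray_level_nonuniformity": (R.sum(axis=1) ** 2).sum() / nr,
        "glrlm_run_length_nonuniformity": (R.sum(axis=0) ** 2).sum() / nr,
        "glrlm_run_percentage": nr / n_voxels,
        "glrlm_low_gray_level_run_emphasis": (R / iv**2).sum() / nr,
        "glrlm_high_gray_level_run_emphasis": (R * iv**2).sum() / nr,
        "glrlm_short_run_low_gray_level_emphasis": (R / (iv**2 * jv**2)).sum() / nr,
        "glrlm_short_run_high_gray_level_emphasis": (R * iv**2 / jv**2).sum() / nr,
        "glrlm_long_run_low_gray_level_emphasis": (R * jv**2 / iv**2).sum() / nr,
        "glrlm_long_run_high_gray_level_emphasis": (R * iv**2 * jv**2).sum() / nr,
    }


# ---------------------------------------------------------------------------
# extraction


def _crop(mask: np.ndarray):
    idx = np.nonzero(mask)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def extract_region_features(
    intensity: np.ndarray,
    labels: np.ndarray,
    region_id: int,
    cfg: TextureMatrixConfig | None = None,
) -> FeatureVector:
    """Extract the 47 canonical features of one labeled region.

    Intensities are discretized over the region's own min-max range with
    ``cfg.n_bins`` fixed bins; GLCM and GLRLM features are averaged over
    ``cfg.offsets``.  A constant-intensity region yields zero variance and
    entropy and single-bin texture matrices.
    """
    cfg = cfg or TextureMatrixConfig()
    intensity = np.asarray(intensity, dtype=float)
    labels = np.asarray(labels)
    if intensity.shape != labels.shape:
        raise ParameterError("intensity and label volumes differ in shape")
    mask = labels == region_id
    if not mask.any():
        raise EmptyRegionError(f"region {region_id} has no voxels")
    box = _crop(mask)
    mask = mask[box]
    vol = intensity[box]
    x = vol[mask]

    values = _first_order(x, cfg.n_bins)

    levels = np.zeros(mask.shape, dtype=np.int64)
    levels[mask] = discretize(x, cfg.n_bins)

    glcm_acc = {k: 0.0 for k in GLCM_FEATURES}
    glrlm_acc = {k: 0.0 for k in GLRLM_FEATURES}
    for off in cfg.offsets:
        P = cooccurrence_matrix(
            levels, mask, off, cfg.n_bins, cfg.symmetric, cfg.normalization
        )
        for k, v in _glcm_features(P).items():
            glcm_acc[k] += v
        R = run_length_matrix(levels, mask, off, cfg.n_bins)
        for k, v in _glrlm_features(R, int(mask.sum())).items():
            glrlm_acc[k] += v
    n_off = len(cfg.offsets)
    values.update({k: v / n_off for k, v in glcm_acc.items()})
    values.update({k: v / n_off for k, v in glrlm_acc.items()})
    values = {k: float(values[k]) for k in CANONICAL_FEATURES}
    return FeatureVector(region_id=int(region_id), n_voxels=int(mask.sum()), values=values)


def extract_subject_features(
    intensity: np.ndarray,
    labels: np.ndarray,
    atlas_regions,
    cfg: TextureMatrixConfig | None = None,
    subject_id: str = "subject",
    atlas_id: str = "synthetic",
    missing: str = "error",
) -> RegionalFeatureMatrix:
    """Extract the regions x 47 feature matrix of one subject.

    Rows follow ``atlas_regions`` order.  A region absent from the label
    volume raises :class:`MissingRegionError` by default, or produces a
    NaN row with ``missing="nan"``.
    """
    cfg = cfg or TextureMatrixConfig()
    atlas_regions = list(atlas_regions)
    rows = []
    for rid in atlas_regions:
        try:
            fv = extract_region_features(intensity, labels, rid, cfg)
            rows.append(fv.as_array())
        except EmptyRegionError:
            if missing == "nan":
                rows.append(np.full(len(CANONICAL_FEATURES), np.nan))
            else:
                raise MissingRegionError(f"atlas region {rid} missing from labels")
    return RegionalFeatureMatrix(
        subject_id=subject_id,
        matrix=np.vstack(rows),
        region_ids=atlas_regions,
        feature_names=list(CANONICAL_FEATURES),
        atlas_id=atlas_id,
    )
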