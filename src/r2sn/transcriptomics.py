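"""Imaging-transcriptomics: relate a regional group-difference map to
regional gene expression with partial least squares.

Gene columns are z-scored across regions and the t-map is centered; the
first PLS component is the gene-space direction maximizing covariance
between the expression projection and the t-map (weights proportional to
X'y).  The component sign is fixed so its correlation with the t-map is
nonnegative.  Significance comes from uniform permutation of the t-map's
region labels.  Variance explained is the share of (standardized)
expression variance captured by the component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, ParameterError

__all__ = [
    "RegionalTMap",
    "PlsResult",
    "pls_first_component",
    "pls_permutation_p",
    "gene_tmap_correlations",
    "export_ranked_genes",
]


@dataclass
class RegionalTMap:
    region_ids: list
    t_values: np.ndarray

    def __post_init__(self):
        self.t_values = np.asarray(self.t_values, dtype=float)
        if len(self.region_ids) != self.t_values.shape[0]:
            raise ParameterError("region_ids and t_values differ in length")
        if not np.all(np.isfinite(self.t_values)):
            raise ParameterError("t-map contains non-finite values")


@dataclass
class PlsResult:
    gene_weights: pd.Series
    region_scores: np.ndarray
    var_explained: float
    r_with_tmap: float
    p_perm: float = None
    dropped_genes: list = field(default_factory=list)


def _standardize(expression: pd.DataFrame):
    X = expression.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = [c for c, k in zip(expression.columns, keep) if not k]
    if dropped:
        warnings.warn(f"{len(dropped)} zero-variance gene(s) dropped")
    if not keep.any():
        raise DegenerateInputError("all genes have zero variance")
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return X, [c for c in expression.columns[keep]], dropped


def pls_first_component(expression: pd.DataFrame, tmap: RegionalTMap) -> PlsResult:
    """First PLS component of standardized expression against the t-map."""
    if expression.shape[0] != len(tmap.region_ids):
        raise ParameterError("expression and t-map cover different regions")
    if expression.shape[0] < 3:
        raise ParameterError("need at least 3 regions")
    X, genes, dropped = _standardize(expression)
    y = tmap.t_values - tmap.t_values.mean()
    w = X.T @ y
    norm = np.linalg.norm(w)
    if norm == 0:
        raise DegenerateInputError("expression is exactly orthogonal to the t-map")
    w = w / norm
    t = X @ w
    # sign convention: positive correlation with the t-map
    r = stats.pearsonr(t, tmap.t_values)[0] if t.std() > 0 else 0.0
    if r < 0:
        w, t, r = -w, -t, -r
    tt = float(t @ t)
    loadings = X.T @ t / tt if tt > 0 else np.zeros_like(w)
    total_var = float((X**2).sum())
    var_explained = float(tt * (loadings @ loadings) / total_var) if total_var else 0.0
    return PlsResult(
        gene_weights=pd.Series(w, index=genes),
        region_scores=t,
        var_explained=var_explained,
        r_with_tmap=float(r),
        dropped_genes=dropped,
    )


def pls_permutation_p(
    expression: pd.DataFrame,
    tmap: RegionalTMap,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p for |r(PLS1, t-map)| under region-label shuffling."""
    obs = abs(pls_first_component(expression, tmap).r_with_tmap)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = RegionalTMap(tmap.region_ids, rng.permutation(tmap.t_values))
        if abs(pls_first_component(expression, perm).r_with_tmap) >= obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def gene_tmap_correlations(
    expression: pd.DataFrame,
    tmap: RegionalTMap,
    gene_names,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Pearson r/p of named genes against the t-map, Bonferroni over the list.

    Missing gene names are reported in the ``missing`` attribute of the
    returned frame and skipped.
    """
    found = [g for g in gene_names if g in expression.columns]
    missing = [g for g in gene_names if g not in expression.columns]
    if missing:
        warnings.warn(f"gene(s) not in expression matrix, skipped: {missing}")
    if not found:
        raise ParameterError("none of the requested genes is present")
    rows = {}
    m = len(found)
    for g in found:
        r, p = stats.pearsonr(expression[g].to_numpy(dtype=float), tmap.t_values)
        p_adj = min(1.0, p * m) if correction == "bonferroni" else p
        rows[g] = {"r": float(r), "p": float(p), "p_adjusted": float(p_adj)}
    out = pd.DataFrame(rows).T
    out.attrs["missing"] = missing
    return out


def export_ranked_genes(result: PlsResult, path) -> list:
    """Write genes ranked by descending PLS weight (ties lexicographic).

    Returns the ordered gene list; the file holds one gene symbol per line
    (enrichment-tool-compatible ranked list).
    """
    w = result.gene_weights
    if not np.all(np.isfinite(w.to_numpy())):
        raise ParameterError("non-finite weights")
    order = sorted(w.index, key=lambda g: (-w[g], g))
    with open(path, "w") as fh:
        for g in order:
            fh.write(f"{g}\n")
    return order
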