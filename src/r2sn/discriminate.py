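"""Group discrimination on network edges.

Edgewise two-sample statistics between diagnostic groups, a linear
large-margin classifier with cross-validated performance, correlations of
classifier decision values with clinical measures, and the selection of
"consistent" connections: edges that are both statistically different
between groups and heavily weighted by the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .exceptions import EmptySelectionError, ParameterError

__all__ = [
    "EdgewiseStats",
    "ClassifierReport",
    "ConsistentEdgeSet",
    "edgewise_ttest",
    "crossvalidated_classifier",
    "decision_value_correlations",
    "select_consistent_edges",
]


@dataclass
class EdgewiseStats:
    t_values: np.ndarray
    p_values: np.ndarray
    p_adjusted: np.ndarray
    group_sizes: tuple
    correction: str = "bonferroni"


@dataclass
class ClassifierReport:
    auc: float
    acc: float
    sen: float
    spe: float
    scheme: str
    fold_assignments: np.ndarray
    decision_values: np.ndarray
    weights: np.ndarray
    evaluated: np.ndarray = field(default=None)


@dataclass
class ConsistentEdgeSet:
    edge_ids: np.ndarray  # integer indices into the canonical edge order
    stat_rule: str
    clf_rule: str


def edgewise_ttest(
    edges_a: np.ndarray,
    edges_b: np.ndarray,
    correction: str = "bonferroni",
    equal_var: bool = True,
) -> EdgewiseStats:
    """Per-edge two-sample two-sided t-test (pooled variance by default).

    Bonferroni adjustment multiplies p by the number of edges, capped at 1.
    Edges with zero pooled variance get t=0, p=1 with a warning.
    """
    a = np.atleast_2d(np.asarray(edges_a, dtype=float))
    b = np.atleast_2d(np.asarray(edges_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ParameterError("need at least 2 subjects per group")
    if a.shape[1] != b.shape[1]:
        raise ParameterError("edge counts differ between groups")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} edge(s) with zero pooled variance; t=0, p=1"
        )
        t[degenerate] = 0.0
        p[degenerate] = 1.0
    if correction == "bonferroni":
        p_adj = np.minimum(1.0, p * a.shape[1])
    elif correction in (None, "none"):
        p_adj = p.copy()
    else:
        raise ParameterError(f"unknown correction: {correction}")
    return EdgewiseStats(
        t_values=t,
        p_values=p,
        p_adjusted=p_adj,
        group_sizes=(a.shape[0], b.shape[0]),
        correction=correction or "none",
    )


def crossvalidated_classifier(
    edges: np.ndarray,
    labels: np.ndarray,
    scheme: str = "kfold",
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
    test_fraction: float = 0.5,
) -> ClassifierReport:
    """Linear SVM separating the two label groups on edge profiles.

    ``scheme="kfold"``: stratified k-fold CV seeded by ``seed``; decision
    values are collected out of fold for every subject, AUC is computed on
    them, ACC/SEN/SPE at decision threshold 0, and the reported weights are
    refit on all data.  ``scheme="split"``: a single stratified train/test
    split; only test subjects are evaluated.
    """
    X = np.asarray(edges, dtype=float)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ParameterError("labels must contain exactly two classes")
    y = (y == classes.max()).astype(int)
    n = X.shape[0]
    dec = np.full(n, np.nan)
    folds = np.full(n, -1)

    def _fit(Xtr, ytr):
        clf = SVC(kernel="linear", C=C)
        clf.fit(Xtr, ytr)
        return clf

    if scheme == "kfold":
        if k > min(np.bincount(y)):
            raise ParameterError("k exceeds the smaller class size")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for f, (tr, te) in enumerate(skf.split(X, y)):
            clf = _fit(X[tr], y[tr])
            dec[te] = clf.decision_function(X[te])
            folds[te] = f
        evaluated = np.ones(n, dtype=bool)
        weights = _fit(X, y).coef_.ravel()
    elif scheme == "split":
        idx = np.arange(n)
        tr, te = train_test_split(
            idx, test_size=test_fraction, stratify=y, random_state=seed
        )
        clf = _fit(X[tr], y[tr])
        dec[te] = clf.decision_function(X[te])
        folds[tr] = 0
        folds[te] = 1
        evaluated = np.zeros(n, dtype=bool)
        evaluated[te] = True
        weights = clf.coef_.ravel()
    else:
        raise ParameterError(f"unknown scheme: {scheme}")

    ye = y[evaluated]
    de = dec[evaluated]
    pred = (de > 0).astype(int)
    auc = float(roc_auc_score(ye, de))
    acc = float((pred == ye).mean())
    sen = float((pred[ye == 1] == 1).mean()) if (ye == 1).any() else float("nan")
    spe = float((pred[ye == 0] == 0).mean()) if (ye == 0).any() else float("nan")
    return ClassifierReport(
        auc=auc,
        acc=acc,
        sen=sen,
        spe=spe,
        scheme=scheme,
        fold_assignments=folds,
        decision_values=dec,
        weights=weights,
        evaluated=evaluated,
    )


def decision_value_correlations(
    decision_values: np.ndarray, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and two-sided p between decision values and each measure.

    Pairwise-complete; measures with fewer than 3 paired observations are
    skipped with a warning.
    """
    d = np.asarray(decision_values, dtype=float)
    rows = {}
    for col in clinical.columns:
        v = pd.to_numeric(clinical[col], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(d) & np.isfinite(v)
        if ok.sum() < 3:
            warnings.warn(f"measure {col!r}: fewer than 3 paired observations; skipped")
            continue
        r, p = stats.pearsonr(d[ok], v[ok])
        rows[col] = {"r": float(r), "p": float(p), "n": int(ok.sum())}
    return pd.DataFrame(rows).T


def select_consistent_edges(
    stats_: EdgewiseStats,
    report: ClassifierReport,
    alpha: float = 0.05,
    top_frac: float = 0.05,
) -> ConsistentEdgeSet:
    """Intersect statistically significant edges with top classifier edges.

    Statistical rule: adjusted p < alpha.  Classifier rule: |weight| in the
    top ``top_frac`` quantile.  An empty intersection raises
    :class:`EmptySelectionError`.
    """
    n = stats_.p_adjusted.shape[0]
    if report.weights.shape[0] != n:
        raise ParameterError("stats and classifier cover different edge sets")
    sig = np.nonzero(stats_.p_adjusted < alpha)[0]
    n_top = max(1, int(np.ceil(top_frac * n)))
    order = np.argsort(-np.abs(report.weights), kind="stable")
    top = set(order[:n_top].tolist())
    chosen = np.array(sorted(set(sig.tolist()) & top), dtype=int)
    if chosen.size == 0:
        raise EmptySelectionError(
            "no edge is both significant and highly weighted; pipeline cannot proceed"
        )
    return ConsistentEdgeSet(
        edge_ids=chosen,
        stat_rule=f"p_adjusted<{alpha} ({stats_.correction})",
        clf_rule=f"|weight| top {top_frac:g} fraction",
    )
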