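"""End-to-end orchestration: feature tables -> networks -> consistent
edges -> MCI subtypes.

The steps mirror the analysis design: min-max normalize each subject,
fit the feature-redundancy screen on the NC reference cohort and apply it
frozen to everyone, build each subject's network, test and classify NC vs
AD on the canonical edge vectors, intersect the two edge selections, and
cluster the MCI subjects' consistent-edge profiles with rank-2 NMF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import discriminate, network, subtype
from .exceptions import ParameterError

__all__ = ["PipelineResult", "edge_matrix", "run_pipeline"]


@dataclass
class PipelineResult:
    retention: network.FeatureRetention
    edge_df: pd.DataFrame  # subjects x canonical edges
    stats: discriminate.EdgewiseStats
    report: discriminate.ClassifierReport
    consistent: discriminate.ConsistentEdgeSet
    assignment: subtype.SubtypeAssignment
    tmap_regions: pd.Series = None  # region-level subtype difference t-map


def edge_matrix(feature_matrices, retention) -> pd.DataFrame:
    """Subjects x canonical-edge DataFrame of network edge weights."""
    rows, ids = [], []
    region_ids = None
    for fm in feature_matrices:
        net = network.build_r2sn(fm, retention)
        ev = network.vectorize_edges(net)
        rows.append(ev.values)
        ids.append(fm.subject_id)
        if region_ids is None:
            region_ids = net.region_ids
        elif region_ids != net.region_ids:
            raise ParameterError("subjects disagree on region order")
    return pd.DataFrame(rows, index=ids, columns=network.edge_ids(region_ids))


def run_pipeline(
    feature_matrices,
    phenotypes: pd.DataFrame,
    alpha: float = 0.05,
    top_frac: float = 0.05,
    retention_threshold: float = 0.9,
    seed: int = 0,
    cv_folds: int = 10,
    n_restarts: int = 20,
) -> PipelineResult:
    """Run the full subtyping pipeline on per-subject feature tables.

    ``phenotypes`` must hold subject_id and diagnosis (NC/MCI/AD) for every
    subject in ``feature_matrices``.
    """
    dx = phenotypes.set_index("subject_id")["diagnosis"]
    normalized = [network.minmax_normalize(fm) for fm in feature_matrices]
    nc_fms = [fm for fm in normalized if dx.get(fm.subject_id) == "NC"]
    if not nc_fms:
        raise ParameterError("no NC subjects to fit the feature-redundancy screen")
    retention = network.fit_feature_retention(
        nc_fms, threshold=retention_threshold, provenance="NC reference cohort"
    )
    edge_df = edge_matrix(normalized, retention)

    grp = dx.reindex(edge_df.index)
    nc_edges = edge_df.loc[grp == "NC"].to_numpy()
    ad_edges = edge_df.loc[grp == "AD"].to_numpy()
    mci_ids = edge_df.index[grp == "MCI"].tolist()
    mci_edges = edge_df.loc[mci_ids].to_numpy()
    if min(len(nc_edges), len(ad_edges)) < 2 or not mci_ids:
        raise ParameterError("need NC, AD, and MCI subjects")

    stats = discriminate.edgewise_ttest(nc_edges, ad_edges)
    X = np.vstack([nc_edges, ad_edges])
    y = np.concatenate([np.zeros(len(nc_edges)), np.ones(len(ad_edges))])
    k = min(cv_folds, int(min(len(nc_edges), len(ad_edges))))
    report = discriminate.crossvalidated_classifier(X, y, scheme="kfold", k=k, seed=seed)
    consistent = discriminate.select_consistent_edges(
        stats, report, alpha=alpha, top_frac=top_frac
    )

    sel = consistent.edge_ids
    mci_profiles = subtype.to_nonnegative(mci_edges[:, sel])
    nc_mean = subtype.to_nonnegative(nc_edges[:, sel]).mean(axis=0)
    ad_mean = subtype.to_nonnegative(ad_edges[:, sel]).mean(axis=0)
    assignment = subtype.nmf_cluster(
        mci_profiles, subject_ids=mci_ids, seed=seed, n_restarts=n_restarts
    )
    assignment = subtype.label_components(assignment, mci_profiles, nc_mean, ad_mean)

    tmap = _regional_tmap(edge_df, mci_ids, assignment)
    return PipelineResult(
        retention=retention,
        edge_df=edge_df,
        stats=stats,
        report=report,
        consistent=consistent,
        assignment=assignment,
        tmap_regions=tmap,
    )


def _regional_tmap(edge_df: pd.DataFrame, mci_ids, assignment) -> pd.Series:
    """Region-level subtype difference map: per-region t of node strength.

    Node strength is the mean edge weight of each region's row; the t
    statistic contrasts A-CI vs N-CI subjects.
    """
    from scipy import stats as sps

    region_ids = sorted(
        {rid for eid in edge_df.columns for rid in eid.split("_")}, key=lambda s: int(s)
    )
    n = len(region_ids)
    pos = {rid: i for i, rid in enumerate(region_ids)}
    strength = np.zeros((len(mci_ids), n))
    counts = np.zeros(n)
    vals = edge_df.loc[mci_ids].to_numpy()
    for j, eid in enumerate(edge_df.columns):
        a, b = eid.split("_")
        strength[:, pos[a]] += vals[:, j]
        strength[:, pos[b]] += vals[:, j]
        counts[pos[a]] += 1
        counts[pos[b]] += 1
    strength /= counts
    a_mask = assignment.labels == subtype.A_CI
    t, _ = sps.ttest_ind(strength[a_mask], strength[~a_mask], axis=0)
    return pd.Series(np.nan_to_num(t, nan=0.0), index=region_ids)
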