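"""Readers and writers for the pipeline's plain-text interchange formats.

Feature tables are regions x features TSV (index column = region id);
networks are square CSV; edge vectors are one row per subject keyed by
canonical edge ids "i_j"; assignments, phenotypes, and truth tables are
CSV; expression and t-maps are TSV.  Volumes use NIfTI-1 via nibabel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import RegionalFeatureMatrix
from .network import EdgeVector, R2SNMatrix, edge_ids

__all__ = [
    "write_feature_matrix",
    "read_feature_matrix",
    "write_network",
    "read_network",
    "write_edge_table",
    "read_edge_table",
    "write_assignment",
    "read_assignment",
    "write_nifti",
    "read_nifti_pair",
    "write_expression",
    "read_expression",
    "write_tmap",
    "read_tmap",
]


def write_feature_matrix(fm: RegionalFeatureMatrix, path) -> None:
    df = fm.to_dataframe()
    df.index.name = "region_id"
    df.to_csv(path, sep="\t")


def read_feature_matrix(path, subject_id=None, atlas_id="unknown") -> RegionalFeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RegionalFeatureMatrix(
        subject_id=subject_id or str(path),
        matrix=df.to_numpy(dtype=float),
        region_ids=df.index.tolist(),
        feature_names=df.columns.tolist(),
        atlas_id=atlas_id,
    )


def write_network(net: R2SNMatrix, path) -> None:
    df = pd.DataFrame(net.matrix, index=net.region_ids, columns=net.region_ids)
    df.index.name = "region_id"
    df.to_csv(path)


def read_network(path, subject_id=None) -> R2SNMatrix:
    df = pd.read_csv(path, index_col=0)
    return R2SNMatrix(
        subject_id=subject_id or str(path),
        matrix=df.to_numpy(dtype=float),
        region_ids=df.index.tolist(),
    )


def write_edge_table(edge_vectors, path) -> None:
    """One row per subject, columns = canonical edge ids."""
    evs = list(edge_vectors)
    cols = edge_ids(evs[0].region_ids)
    df = pd.DataFrame(
        [ev.values for ev in evs], index=[ev.subject_id for ev in evs], columns=cols
    )
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t")


def read_edge_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_assignment(assignment, path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": assignment.subject_ids,
            "label": assignment.labels,
            "p_adlike": assignment.p_adlike,
            "coef_0": assignment.coefficients[:, 0],
            "coef_1": assignment.coefficients[:, 1],
        }
    )
    df.to_csv(path, index=False)


def read_assignment(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_nifti(array, path, affine=None) -> None:
    import nibabel as nib

    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(array), affine)
    nib.save(img, str(path))


def read_nifti_pair(intensity_path, labels_path):
    import nibabel as nib

    intensity = np.asarray(nib.load(str(intensity_path)).dataobj, dtype=float)
    labels = np.asarray(nib.load(str(labels_path)).dataobj).astype(np.int64)
    if intensity.shape != labels.shape:
        raise ValueError("intensity and label volumes differ in shape")
    return intensity, labels


def write_expression(expression: pd.DataFrame, path) -> None:
    out = expression.copy()
    out.index.name = "region"
    out.to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tmap(tmap, path) -> None:
    pd.DataFrame({"region_id": tmap.region_ids, "t": tmap.t_values}).to_csv(
        path, sep="\t", index=False
    )


def read_tmap(path):
    from .transcriptomics import RegionalTMap

    df = pd.read_csv(path, sep="\t")
    return RegionalTMap(df["region_id"].tolist(), df["t"].to_numpy(dtype=float))
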