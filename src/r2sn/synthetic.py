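"""Synthetic cohorts, labeled volumes, and expression matrices.

The generator emulates the statistical structure the analysis assumes,
so every downstream stage is testable without access to gated data:

* three diagnostic groups (NC / MCI / AD) whose regional feature profiles
  make AD-like networks separable from NC-like ones.  The latent AD
  pattern is an additive, feature-heterogeneous downward shift applied to
  a fixed 20% subset of regions (an atrophy analog);
* an MCI group drawn as a mixture of the two patterns;
* annual follow-up visits with pattern-dependent cognitive decline and
  exponential conversion hazards (administratively censored at the last
  visit);
* a regions x genes expression matrix with a planted subset of columns
  spatially correlated with a supplied regional statistic map.

Latent truth (pattern labels, true conversion times, affected regions,
signal genes) is emitted only into separate truth tables, never into the
phenotype columns the pipeline consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .features import RegionalFeatureMatrix

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_labeled_volume",
    "generate_expression",
    "perturb_features",
]

# (NC mean, AD mean, within-group sd) per clinical measure, patterned on a
# typical aging/dementia cohort; MCI draws sit between the anchors.
_MEASURES = {
    "mmse": (29.1, 23.2, 1.6),
    "phs": (0.05, 0.81, 0.8),
    "fdg": (1.31, 1.07, 0.13),
    "csf_abeta": (1037.0, 623.0, 280.0),
    "csf_tau": (240.0, 368.0, 120.0),
    "csf_ptau": (22.1, 36.9, 13.0),
    "adas_cog11": (7.0, 19.7, 4.0),
    "adas_cog13": (10.4, 30.0, 5.5),
    "avlt1": (45.3, 23.1, 9.0),
    "avlt2": (6.1, 2.0, 2.0),
}
# interpolation weight toward the AD anchor for MCI of each latent pattern
_W_ADLIKE = 0.65
_W_NCLIKE = 0.25

# annual decline rates for follow-up measures (per latent pattern)
_DECLINE = {
    # measure: (NC-like rate, AD-like rate, visit noise sd)
    "mmse": (-0.3, -1.3, 0.7),
    "cdr": (0.08, 0.35, 0.15),
    "adas_cog13": (0.6, 3.0, 1.5),
}

# baseline annual conversion hazard of NC-like MCI; together with the
# default hazard ratio this puts three-year conversion near 22% and 62%
# for the two patterns.
_BASE_HAZARD = -math.log(1 - 0.2177) / 3.0


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of a synthetic cohort."""

    n_nc: int = 605
    n_mci: int = 766
    n_ad: int = 283
    n_regions: int = 246
    n_features: int = 47
    effect_size: float = 2.0
    frac_mci_adlike: float = 0.67
    noise_sd: float = 0.5
    seed: int = 0
    n_visits: int = 6
    hazard_ratio_adlike: float = 3.9

    def __post_init__(self):
        for name in ("n_nc", "n_mci", "n_ad", "n_regions", "n_features", "n_visits"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0 <= self.frac_mci_adlike <= 1:
            raise ParameterError("frac_mci_adlike must be in [0, 1]")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.hazard_ratio_adlike <= 0:
            raise ParameterError("hazard_ratio_adlike must be > 0")


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    feature_matrices: list
    phenotypes: pd.DataFrame
    visits: pd.DataFrame
    truth: pd.DataFrame
    affected_regions: np.ndarray
    shift_profile: np.ndarray = field(default=None, repr=False)
    template: np.ndarray = field(default=None, repr=False)

    def subjects(self, diagnosis: str) -> list:
        return self.phenotypes.loc[
            self.phenotypes["diagnosis"] == diagnosis, "subject_id"
        ].tolist()


def _feature_names(n: int) -> list:
    from .features import CANONICAL_FEATURES

    if n == len(CANONICAL_FEATURES):
        return list(CANONICAL_FEATURES)
    return [f"f{i:03d}" for i in range(1, n + 1)]


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort from a :class:`CohortSpec`.

    Deterministic: the same spec yields byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    R, F = spec.n_regions, spec.n_features
    region_ids = list(range(1, R + 1))
    feature_names = _feature_names(F)

    template = rng.normal(0.0, 1.0, (R, F))
    n_affected = max(1, math.ceil(0.2 * R))
    affected = np.sort(rng.choice(R, size=n_affected, replace=False))
    # feature-heterogeneous shift: changes the *shape* of affected regions'
    # profiles, hence their correlations with other regions
    shift_profile = rng.uniform(0.5, 1.5, F)

    groups = ["NC"] * spec.n_nc + ["MCI"] * spec.n_mci + ["AD"] * spec.n_ad
    adlike_flags = []
    for g in groups:
        if g == "NC":
            adlike_flags.append(False)
        elif g == "AD":
            adlike_flags.append(True)
        else:
            adlike_flags.append(bool(rng.random() < spec.frac_mci_adlike))

    fms, pheno_rows, visit_rows, truth_rows = [], [], [], []
    for idx, (g, adlike) in enumerate(zip(groups, adlike_flags)):
        sid = f"S{idx:04d}"
        M = template.copy()
        if adlike:
            M[affected, :] -= spec.effect_size * shift_profile
        M += rng.normal(0.0, spec.noise_sd, (R, F))
        fms.append(
            RegionalFeatureMatrix(
                subject_id=sid,
                matrix=M,
                region_ids=region_ids,
                feature_names=feature_names,
                atlas_id=f"synthetic-{R}",
            )
        )

        if g == "NC":
            age = rng.normal(73.5, 6.2)
        elif g == "AD":
            age = rng.normal(74.9, 7.7)
        else:
            age = rng.normal(75.1, 7.0) if adlike else rng.normal(68.6, 7.3)
        sex = "M" if rng.random() < 0.5 else "F"
        row = {"subject_id": sid, "diagnosis": g, "age": float(age), "sex": sex}
        if g == "NC":
            w = 0.0
        elif g == "AD":
            w = 1.0
        else:
            w = _W_ADLIKE if adlike else _W_NCLIKE
        for m, (nc_mu, ad_mu, sd) in _MEASURES.items():
            row[m] = float(nc_mu + w * (ad_mu - nc_mu) + rng.normal(0.0, sd))
        pheno_rows.append(row)

        # follow-up: annual visits, conversion hazard by latent pattern
        conv_months = np.nan
        if g == "MCI":
            lam = _BASE_HAZARD * (spec.hazard_ratio_adlike if adlike else 1.0)
            conv_months = float(rng.exponential(1.0 / lam) * 12.0)
            rate_w = 1.0 if adlike else 0.0
            base_cdr = 0.5
            for k in range(spec.n_visits + 1):
                months = 12.0 * k
                dx = "AD" if months >= conv_months else "MCI"
                vr = {"subject_id": sid, "months": months, "diagnosis": dx}
                for m, (r_nc, r_ad, vsd) in _DECLINE.items():
                    rate = r_nc + rate_w * (r_ad - r_nc)
                    base = row.get(m, base_cdr if m == "cdr" else 0.0)
                    vr[m] = float(base + rate * k + rng.normal(0.0, vsd))
                visit_rows.append(vr)
        truth_rows.append(
            {
                "subject_id": sid,
                "diagnosis": g,
                "adlike": adlike,
                "conversion_months": conv_months,
            }
        )

    phenotypes = pd.DataFrame(pheno_rows)
    visits = pd.DataFrame(visit_rows)
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(
        spec=spec,
        feature_matrices=fms,
        phenotypes=phenotypes,
        visits=visits,
        truth=truth,
        affected_regions=affected + 1,  # region ids are 1-based
        shift_profile=shift_profile,
        template=template,
    )


def generate_labeled_volume(n_regions: int, shape, seed: int = 0):
    """A compact 3D intensity volume plus contiguous integer parcellation.

    The grid's voxels (raster order) are split into ``n_regions`` chunks of
    near-equal size labeled 1..n_regions.  Each region's intensity has its
    own mean, spread, and lattice-parity texture amplitude, so texture
    features differ between regions.  Deterministic given the seed.
    """
    if n_regions < 2:
        raise ParameterError("n_regions must be >= 2")
    shape = tuple(int(s) for s in shape)
    n_vox = int(np.prod(shape))
    if n_vox // n_regions < 27:
        raise ParameterError(
            f"grid {shape} too small: each of {n_regions} regions needs >= 27 voxels"
        )
    rng = np.random.default_rng(seed)
    flat = np.minimum(
        (np.arange(n_vox) * n_regions) // n_vox, n_regions - 1
    ).astype(np.int32) + 1
    labels = flat.reshape(shape)

    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    parity = ((zz + yy + xx) % 2) * 2.0 - 1.0
    means = rng.uniform(50.0, 150.0, n_regions)
    sds = rng.uniform(4.0, 15.0, n_regions)
    amps = rng.uniform(0.0, 12.0, n_regions)
    intensity = (
        means[labels - 1]
        + amps[labels - 1] * parity
        + rng.normal(0.0, 1.0, shape) * sds[labels - 1]
    )
    return intensity, labels


def generate_expression(
    tvals: np.ndarray,
    n_genes: int,
    n_signal: int,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Regions x genes expression with a planted t-map-correlated subset.

    Returns ``(expression, truth)``: a DataFrame with gene-symbol columns,
    and a truth DataFrame marking the signal genes and their (positive)
    slopes.  Signal columns are ``a * tvals + noise``; the rest pure noise.
    """
    tvals = np.asarray(tvals, dtype=float)
    if n_signal > n_genes:
        raise ParameterError("n_signal cannot exceed n_genes")
    if n_genes <= 0:
        raise ParameterError("n_genes must be > 0")
    rng = np.random.default_rng(seed)
    n_regions = tvals.shape[0]
    names = [f"GENE{i:05d}" for i in range(1, n_genes + 1)]
    signal_idx = rng.choice(n_genes, size=n_signal, replace=False) if n_signal else []
    slopes = np.zeros(n_genes)
    X = rng.normal(0.0, 1.0, (n_regions, n_genes)) * noise_sd
    for j in signal_idx:
        a = rng.uniform(0.5, 1.5)
        slopes[j] = a
        X[:, j] = a * tvals + rng.normal(0.0, noise_sd, n_regions)
    expression = pd.DataFrame(X, columns=names)
    truth = pd.DataFrame(
        {"gene": names, "is_signal": slopes > 0, "slope": slopes}
    )
    return expression, truth


def perturb_features(
    feature_matrices, noise_sd: float = 0.3, seed: int = 0
) -> list:
    """Re-measure feature matrices with independent noise.

    Emulates extracting the same subjects under a perturbed parcellation
    or re-measurement: adds iid Gaussian noise to every cell.
    """
    rng = np.random.default_rng(seed)
    out = []
    for fm in feature_matrices:
        new = fm.copy()
        new.matrix = new.matrix + rng.normal(0.0, noise_sd, new.matrix.shape)
        out.append(new)
    return out
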