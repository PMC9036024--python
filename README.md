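# r2sn — regional radiomics similarity networks

`r2sn` builds individual morphological brain networks from regional
radiomics features and uses them to stratify patients with mild cognitive
impairment (MCI) into data-driven subtypes, characterize those subtypes
clinically, and relate the subtype difference map to regional gene
expression. It is aimed at neuroimaging researchers studying
heterogeneity in the Alzheimer's disease (AD) continuum, and at anyone who
wants a fully testable, synthetic-data-backed implementation of this
family of analyses.

## The model

For each subject, 47 radiomics features (14 first-order intensity
statistics, 22 GLCM and 11 GLRLM texture features) are extracted from
every region of a co-registered parcellation. After per-subject min-max
normalization of each feature across regions and greedy pruning of
redundant features (|r| > 0.9 on a normal-control reference cohort), the
**regional radiomics similarity network** is the matrix

> R(i, j) = Pearson correlation of the retained-feature vectors of
> regions i and j,

a symmetric, unit-diagonal network per subject. Downstream:

1. **Discrimination** — per-edge two-sample t-tests (Bonferroni) between
   normal controls (NC) and AD, plus a linear SVM with stratified
   ten-fold cross-validation; *consistent connections* are the edges that
   are both statistically significant and in the top fraction of
   |SVM weight|.
2. **Subtyping** — MCI subjects' consistent-connection profiles, mapped
   to [0, 1] by x ↦ (x+1)/2, are factorized by rank-2 multiplicative-
   update NMF; the component whose weighted centroid lies closer to the
   AD mean profile is labeled **A-CI** (AD-like), the other **N-CI**.
3. **Characterization** — clinical contrasts (pooled t, label-permutation
   p), CSF amyloid/tau categories (Aβ+ iff Aβ < 980 pg/mL, Tau+ iff
   Tau > 245 pg/mL), windowed conversion proportions, Kaplan–Meier
   curves, a risk-set log-rank test, and covariate-adjusted longitudinal
   trajectories.
4. **Transcriptomics** — the first PLS component of regions × genes
   expression against the regional subtype-difference t-map
   (weights ∝ Xᵀy), with region-permutation significance and a ranked
   gene-list export.

A synthetic module generates cohorts with a planted AD pattern (a
feature-heterogeneous shift on 20% of regions), pattern-dependent
conversion hazards and cognitive decline, and expression matrices with
planted t-map-correlated genes, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from r2sn import synthetic as syn, pipeline as pl, characterize as chz
from r2sn import transcriptomics as trx

spec = syn.CohortSpec(n_nc=50, n_mci=60, n_ad=50, n_regions=60,
                      n_features=47, effect_size=2.0,
                      frac_mci_adlike=0.6, noise_sd=0.5, seed=7)
cohort = syn.generate_cohort(spec)
res = pl.run_pipeline(cohort.feature_matrices, cohort.phenotypes, seed=7)
n_a = int((res.assignment.labels == "A-CI").sum())
print(f"NC-vs-AD classifier AUC: {res.report.auc:.2f}")
print(f"consistent edges: {res.consistent.edge_ids.size} / {res.edge_df.shape[1]}")
print(f"subtypes: A-CI n={n_a}, N-CI n={len(res.assignment.labels) - n_a}")

ids, surv = chz.survival_from_visits(cohort.visits)
lab = dict(zip(res.assignment.subject_ids, res.assignment.labels))
la = np.array([lab.get(i, "") for i in ids])
sa = chz.SurvivalData(surv.time[la == "A-CI"], surv.event[la == "A-CI"])
sn = chz.SurvivalData(surv.time[la == "N-CI"], surv.event[la == "N-CI"])
ca, cn = chz.conversion_proportion(sa), chz.conversion_proportion(sn)
print(f"3-year conversion: A-CI {100*ca[2]:.1f}% ({ca[0]}/{ca[1]}), "
      f"N-CI {100*cn[2]:.1f}% ({cn[0]}/{cn[1]})")
chi2, p = chz.logrank_test(sa, sn)
print(f"log-rank: chi2={chi2:.1f}, p={p:.2e}")

tvals = res.tmap_regions.to_numpy()
expr, _ = syn.generate_expression(tvals, n_genes=100, n_signal=10,
                                  noise_sd=1.0, seed=77)
tm = trx.RegionalTMap(list(res.tmap_regions.index), tvals)
pls = trx.pls_first_component(expr, tm)
p_perm = trx.pls_permutation_p(expr, tm, n_perm=1000, seed=7)
print(f"PLS1: r={pls.r_with_tmap:.2f}, var explained={pls.var_explained:.2f}, "
      f"p_perm={p_perm:.3g}")
```

prints (numbers produced by this exact script):

```
NC-vs-AD classifier AUC: 1.00
consistent edges: 74 / 1770
subtypes: A-CI n=37, N-CI n=23
3-year conversion: A-CI 48.6% (18/37), N-CI 8.7% (2/23)
log-rank: chi2=16.3, p=5.31e-05
PLS1: r=0.99, var explained=0.11, p_perm=0.000999
```

Reading: the classifier separates the synthetic NC and AD networks
perfectly (AUC 1.0); 74 of 1770 edges are "consistent"; NMF splits the 60
MCI subjects into an AD-like group that converts to dementia about five
times as often within three years, with a correspondingly significant
log-rank test; and the first PLS component of the planted expression
matrix is almost perfectly aligned with the subtype difference map.

There is also a CLI (`r2sn simulate / extract / build-network /
discriminate / subtype / characterize / transcriptomics`); run
`r2sn --help` for details.

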