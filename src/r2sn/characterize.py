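"""Subtype characterization: clinical contrasts, CSF biomarker categories,
conversion and survival analysis, longitudinal trajectories.

Conversion is the first follow-up visit with an AD diagnosis; time is
months from baseline, censored at the last visit.  The log-rank test is
computed from risk-set sums; Kaplan-Meier estimation uses the standard
product-limit estimator.  CSF amyloid/tau positivity uses the ADNI cut
points (amyloid-beta < 980 pg/mL, tau > 245 pg/mL).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .exceptions import DegenerateInputError, ParameterError

__all__ = [
    "SurvivalData",
    "CSF_BOTH_POS",
    "CSF_MIXED",
    "CSF_BOTH_NEG",
    "compare_groups",
    "label_permutation_test",
    "csf_categorize",
    "contingency_test",
    "conversion_proportion",
    "km_estimate",
    "logrank_test",
    "survival_label_permutation",
    "adjusted_trajectories",
    "cross_cohort_consistency",
]

CSF_BOTH_POS = "Abeta+&Tau+"
CSF_MIXED = "Abeta-&Tau+/Abeta+&Tau-"
CSF_BOTH_NEG = "Abeta-&Tau-"


@dataclass
class SurvivalData:
    """Months to AD conversion (event=True) or censoring (event=False)."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if self.time.shape != self.event.shape:
            raise ParameterError("time and event differ in length")
        if (self.time <= 0).any():
            raise ParameterError("survival times must be positive")


def survival_from_visits(visits: pd.DataFrame):
    """Derive conversion survival data from a long-format visit table.

    Conversion is the first visit with an AD diagnosis; time is months from
    baseline (censored at the last visit).  Baseline-only AD diagnoses are
    treated as immediate events at the first follow-up.  Returns
    ``(subject_ids, SurvivalData)`` in subject order of first appearance.
    """
    needed = {"subject_id", "months", "diagnosis"}
    if not needed.issubset(visits.columns):
        raise ParameterError(f"visit table must contain {sorted(needed)}")
    ids, times, events = [], [], []
    for sid, grp in visits.groupby("subject_id", sort=False):
        grp = grp.sort_values("months")
        months = grp["months"].to_numpy(dtype=float)
        ad = grp["diagnosis"].astype(str).to_numpy() == "AD"
        ids.append(sid)
        if ad.any():
            t = months[ad][0]
            times.append(t if t > 0 else months[months > 0][0] if (months > 0).any() else 1.0)
            events.append(True)
        else:
            times.append(months[-1] if months[-1] > 0 else 1.0)
            events.append(False)
    return ids, SurvivalData(np.array(times), np.array(events))


def compare_groups(a, b, equal_var: bool = True):
    """Two-sample two-sided t-test (pooled variance); missing values dropped."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ParameterError("need at least 2 observations per group")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if not np.isfinite(t):  # zero pooled variance
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0  # no difference at all
        else:  # perfectly separated constant groups
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    return float(t), float(p)


def label_permutation_test(
    measure, labels, n_perm: int = 1000, seed: int = 0
) -> float:
    """Permutation p of the two-group t statistic under label shuffling.

    p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1); never returns 0.
    """
    x = np.asarray(measure, dtype=float)
    g = np.asarray(labels)
    ok = np.isfinite(x)
    x, g = x[ok], g[ok]
    groups = np.unique(g)
    if groups.size != 2:
        raise ParameterError("labels must contain exactly two groups")
    if np.all(x == x[0]):
        raise DegenerateInputError("constant measure")
    t_obs, _ = compare_groups(x[g == groups[0]], x[g == groups[1]])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        gp = rng.permutation(g)
        t_p, _ = compare_groups(x[gp == groups[0]], x[gp == groups[1]])
        if abs(t_p) >= abs(t_obs):
            count += 1
    return (1 + count) / (n_perm + 1)


def csf_categorize(abeta, tau, abeta_cut: float = 980.0, tau_cut: float = 245.0):
    """CSF biomarker category from amyloid-beta and tau levels (pg/mL).

    Amyloid positive iff abeta < abeta_cut; tau positive iff tau > tau_cut.
    Missing input yields None.
    """
    if abeta is None or tau is None:
        return None
    abeta = float(abeta)
    tau = float(tau)
    if not (np.isfinite(abeta) and np.isfinite(tau)):
        return None
    if abeta <= 0 or tau <= 0:
        raise ParameterError("CSF levels must be positive")
    apos = abeta < abeta_cut
    tpos = tau > tau_cut
    if apos and tpos:
        return CSF_BOTH_POS
    if apos or tpos:
        return CSF_MIXED
    return CSF_BOTH_NEG


def contingency_test(counts):
    """Pearson chi-square of independence (no continuity correction)."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ParameterError("counts must be a nonnegative 2D table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ParameterError("zero margin in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def conversion_proportion(survival: SurvivalData, window: float = 36.0):
    """Converted / at-risk within a follow-up window (months).

    At risk: converted within the window, or followed (censored) at least to
    the window.  Subjects censored before the window are excluded.
    """
    if window <= 0:
        raise ParameterError("window must be positive")
    converted = survival.event & (survival.time <= window)
    at_risk = converted | (survival.time >= window)
    n_risk = int(at_risk.sum())
    if n_risk == 0:
        raise DegenerateInputError("no subject at risk within the window")
    n_conv = int(converted.sum())
    return n_conv, n_risk, n_conv / n_risk


def km_estimate(survival: SurvivalData) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve: columns time, survival.

    S(0) = 1; right-censoring handled; the curve is non-increasing.
    """
    if survival.time.size == 0:
        raise ParameterError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(survival.time, event_observed=survival.event)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank_test(group_a: SurvivalData, group_b: SurvivalData):
    """Standard two-group log-rank chi-square (1 df) from risk-set sums."""
    if group_a.time.size == 0 or group_b.time.size == 0:
        raise ParameterError("both groups must be nonempty")
    times = np.concatenate([group_a.time, group_b.time])
    events = np.concatenate([group_a.event, group_b.event])
    ingroup_a = np.concatenate(
        [np.ones(group_a.time.size, bool), np.zeros(group_b.time.size, bool)]
    )
    if not events.any():
        raise DegenerateInputError("no events in either group")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & ingroup_a).sum()
        d = (events & (times == t)).sum()
        d_a = (events & (times == t) & ingroup_a).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class PermutationSurvivalResult:
    p_observed: float
    p_empirical: float
    perm_p_values: np.ndarray


def survival_label_permutation(
    survival: SurvivalData, labels, n_perm: int = 1000, seed: int = 0
) -> PermutationSurvivalResult:
    """Log-rank significance under group-label permutation.

    Returns the observed log-rank p, the distribution of permuted p-values,
    and the empirical p = (1 + #{chi2_perm >= chi2_obs}) / (n_perm + 1).
    """
    g = np.asarray(labels)
    groups = np.unique(g)
    if groups.size != 2:
        raise ParameterError("labels must contain exactly two groups")

    def _split(lab):
        a = lab == groups[0]
        return (
            SurvivalData(survival.time[a], survival.event[a]),
            SurvivalData(survival.time[~a], survival.event[~a]),
        )

    chi2_obs, p_obs = logrank_test(*_split(g))
    rng = np.random.default_rng(seed)
    count = 0
    perm_p = np.empty(n_perm)
    for i in range(n_perm):
        gp = rng.permutation(g)
        chi2_p, perm_p[i] = logrank_test(*_split(gp))
        if chi2_p >= chi2_obs:
            count += 1
    return PermutationSurvivalResult(
        p_observed=p_obs,
        p_empirical=(1 + count) / (n_perm + 1),
        perm_p_values=perm_p,
    )


def adjusted_trajectories(
    visits: pd.DataFrame,
    baseline: pd.DataFrame,
    groups: pd.Series,
    measure: str,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-group mean +/- sd of a measure at each annual follow-up visit.

    With ``adjust``, the measure is residualized against age and sex via a
    linear fit estimated on the baseline records of all subjects; the same
    coefficients are applied at every visit.  Visit months are binned to
    the nearest year.  Empty bins are omitted with a warning.

    ``visits`` is long-format with columns subject_id, months, and the
    measure; ``baseline`` has subject_id, age, sex and the measure;
    ``groups`` maps subject_id -> group label.
    """
    needed = {"subject_id", "months", measure}
    if not needed.issubset(visits.columns):
        raise ParameterError(f"visits table must contain {sorted(needed)}")
    v = visits[["subject_id", "months", measure]].dropna().copy()
    if adjust:
        base = baseline.dropna(subset=["age", "sex", measure])
        sex_num = (base["sex"].astype(str) == "F").astype(float)
        Z = np.column_stack(
            [np.ones(len(base)), base["age"].to_numpy(dtype=float), sex_num]
        )
        coef, *_ = np.linalg.lstsq(Z, base[measure].to_numpy(dtype=float), rcond=None)
        covar = baseline.set_index("subject_id")[["age", "sex"]]
        v = v[v["subject_id"].isin(covar.index)]
        age = covar.loc[v["subject_id"], "age"].to_numpy(dtype=float)
        sexf = (covar.loc[v["subject_id"], "sex"].astype(str) == "F").astype(float)
        v[measure] = v[measure].to_numpy(dtype=float) - (
            coef[0] + coef[1] * age + coef[2] * sexf.to_numpy()
        )
    v["year"] = np.rint(v["months"].to_numpy(dtype=float) / 12.0).astype(int)
    v["group"] = groups.reindex(v["subject_id"]).to_numpy()
    v = v.dropna(subset=["group"])
    out = (
        v.groupby(["group", "year"])[measure]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    all_years = set(v["year"])
    for grp in out["group"].unique():
        missing = all_years - set(out.loc[out["group"] == grp, "year"])
        if missing:
            warnings.warn(f"group {grp!r}: empty visit bin(s) {sorted(missing)} omitted")
    return out


def cross_cohort_consistency(stats_a, stats_b):
    """Pearson (r, p) between two cohorts' per-item t-values."""
    a = np.asarray(stats_a, dtype=float)
    b = np.asarray(stats_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ParameterError("need two aligned vectors with at least 3 items")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
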