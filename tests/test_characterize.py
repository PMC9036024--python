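"""Clinical contrasts, CSF categories, conversion, survival, trajectories."""

import numpy as np
import pandas as pd
import pytest

from r2sn import characterize as chz
from r2sn.exceptions import DegenerateInputError, ParameterError

from _oracles import km_hand


class TestCompareGroups:
    def test_identical_samples_null(self):
        t, p = chz.compare_groups([1.0, 1, 1], [1.0, 1, 1])
        assert t == 0.0 and p == 1.0

    def test_pooled_t_hand_example(self):
        t, p = chz.compare_groups([1.0, 2, 3], [4.0, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=1e-3)

    def test_missing_values_dropped(self):
        t1, p1 = chz.compare_groups([1.0, 2, 3, np.nan], [4.0, 5, 6])
        t2, p2 = chz.compare_groups([1.0, 2, 3], [4.0, 5, 6])
        assert t1 == t2 and p1 == p2


class TestLabelPermutation:
    def test_maximal_statistic_minimal_p(self):
        labels = np.repeat(["a", "b"], 30)
        measure = (labels == "a").astype(float)  # measure = label indicator
        p = chz.label_permutation_test(measure, labels, n_perm=200, seed=0)
        assert p == pytest.approx(1 / 201)

    def test_null_measure_calibrated(self):
        """Under independence Pr(p <= 0.05) stays near 0.05."""
        hits = 0
        n_rep = 120
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            measure = rng.normal(size=30)
            labels = np.repeat(["a", "b"], 15)
            p = chz.label_permutation_test(measure, labels, n_perm=99, seed=rep)
            hits += p <= 0.05
        assert hits / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_deterministic_given_seed(self, rng):
        m = rng.normal(size=20)
        lab = np.repeat(["a", "b"], 10)
        assert chz.label_permutation_test(m, lab, 100, seed=9) == chz.label_permutation_test(
            m, lab, 100, seed=9
        )

    def test_constant_measure_rejected(self):
        with pytest.raises(DegenerateInputError):
            chz.label_permutation_test([1.0] * 10, np.repeat(["a", "b"], 5))


class TestCsfCategories:
    @pytest.mark.parametrize(
        "abeta,tau,expected",
        [
            (900, 300, chz.CSF_BOTH_POS),
            (1000, 200, chz.CSF_BOTH_NEG),
            (900, 200, chz.CSF_MIXED),
            (1000, 300, chz.CSF_MIXED),
        ],
    )
    def test_threshold_mapping(self, abeta, tau, expected):
        assert chz.csf_categorize(abeta, tau) == expected

    def test_missing_input_gives_missing_category(self):
        assert chz.csf_categorize(np.nan, 300) is None
        assert chz.csf_categorize(None, 300) is None


class TestContingency:
    def test_independence_null(self):
        chi2, p = chz.contingency_test([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0

    def test_doubling_cells_doubles_chi2(self, rng):
        table = rng.integers(5, 50, (2, 3))
        chi2, _ = chz.contingency_test(table)
        chi2x2, _ = chz.contingency_test(2 * table)
        assert chi2x2 == pytest.approx(2 * chi2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ParameterError):
            chz.contingency_test([[0, 0], [5, 5]])


class TestConversionProportion:
    def test_window_accounting(self):
        # 3 converters within window, 1 late censor, 1 early censor (excluded)
        s = chz.SurvivalData([12, 24, 36, 48, 20], [True, True, True, False, False])
        n_conv, n_risk, prop = chz.conversion_proportion(s, window=36)
        assert (n_conv, n_risk) == (3, 4)
        assert prop == pytest.approx(0.75)

    def test_all_censored_before_window_rejected(self):
        s = chz.SurvivalData([10, 20], [False, False])
        with pytest.raises(DegenerateInputError):
            chz.conversion_proportion(s, window=36)


class TestKaplanMeier:
    def test_two_events_by_hand(self):
        s = chz.SurvivalData([1.0, 2.0], [True, True])
        km = chz.km_estimate(s).set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(0.5)
        assert km.loc[2.0] == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        s = chz.SurvivalData([5.0, 9.0, 11.0], [False, False, False])
        km = chz.km_estimate(s)
        np.testing.assert_allclose(km["survival"], 1.0)

    def test_matches_risk_set_oracle(self, rng):
        times = rng.integers(1, 20, 10).astype(float)
        events = rng.random(10) > 0.4
        km = chz.km_estimate(chz.SurvivalData(times, events)).set_index("time")[
            "survival"
        ]
        for t, s in km_hand(times, events):
            assert km.loc[t] == pytest.approx(s), t

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.integers(1, 15, 12).astype(float)
        s = chz.SurvivalData(times, np.ones(12, bool))
        km = chz.km_estimate(s)
        for t, surv in zip(km["time"], km["survival"]):
            assert surv == pytest.approx((times > t).mean())


class TestLogRank:
    def test_identical_groups_null(self):
        s = chz.SurvivalData([3.0, 5.0, 8.0], [True, True, False])
        chi2, p = chz.logrank_test(s, s)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_risk_set_example(self):
        """Frozen worked example: O-E = 1/15, V = 0.74 + 2/9."""
        a = chz.SurvivalData([6.0, 7.0, 10.0], [True, True, False])
        b = chz.SurvivalData([5.0, 8.0, 12.0], [True, True, True])
        chi2, p = chz.logrank_test(a, b)
        expected_chi2 = (1.0 / 15.0) ** 2 / (0.74 + 2.0 / 9.0)
        assert chi2 == pytest.approx(expected_chi2, rel=1e-12)
        assert p == pytest.approx(0.9458152736705872, rel=1e-9)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        ta = rng.exponential(10, 40)
        tb = rng.exponential(5, 35)
        ea = rng.random(40) > 0.3
        eb = rng.random(35) > 0.3
        chi2, p = chz.logrank_test(chz.SurvivalData(ta, ea), chz.SurvivalData(tb, eb))
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_separated_hazards_power(self):
        detected = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            ta = rng.exponential(2.0, 100)
            tb = rng.exponential(10.0, 100)
            _, p = chz.logrank_test(
                chz.SurvivalData(ta, np.ones(100, bool)),
                chz.SurvivalData(tb, np.ones(100, bool)),
            )
            detected += p < 0.001
        assert detected >= 19

    def test_no_events_rejected(self):
        s = chz.SurvivalData([1.0, 2.0], [False, False])
        with pytest.raises(DegenerateInputError):
            chz.logrank_test(s, s)


class TestSurvivalPermutation:
    def test_planted_hazard_ratio_minimal_empirical_p(self, rng):
        times = np.concatenate([rng.exponential(2, 60), rng.exponential(20, 60)])
        events = np.ones(120, bool)
        labels = np.repeat(["fast", "slow"], 60)
        res = chz.survival_label_permutation(
            chz.SurvivalData(times, events), labels, n_perm=200, seed=0
        )
        assert res.p_empirical == pytest.approx(1 / 201)
        assert res.perm_p_values.shape == (200,)

    def test_null_cohort_calibrated(self):
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            times = rng.exponential(5, 40)
            events = rng.random(40) > 0.2
            labels = np.repeat(["a", "b"], 20)
            res = chz.survival_label_permutation(
                chz.SurvivalData(times, events), labels, n_perm=99, seed=rep
            )
            hits += res.p_empirical <= 0.05
        assert hits / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_deterministic_given_seed(self, rng):
        times = rng.exponential(5, 30)
        events = np.ones(30, bool)
        labels = np.repeat(["a", "b"], 15)
        s = chz.SurvivalData(times, events)
        r1 = chz.survival_label_permutation(s, labels, n_perm=50, seed=4)
        r2 = chz.survival_label_permutation(s, labels, n_perm=50, seed=4)
        assert r1.p_empirical == r2.p_empirical
        np.testing.assert_array_equal(r1.perm_p_values, r2.perm_p_values)


class TestSurvivalFromVisits:
    def test_first_ad_visit_defines_conversion(self):
        visits = pd.DataFrame(
            {
                "subject_id": ["s1"] * 3 + ["s2"] * 3,
                "months": [0, 12, 24] * 2,
                "diagnosis": ["MCI", "AD", "AD", "MCI", "MCI", "MCI"],
            }
        )
        ids, surv = chz.survival_from_visits(visits)
        assert ids == ["s1", "s2"]
        assert surv.time.tolist() == [12.0, 24.0]
        assert surv.event.tolist() == [True, False]


class TestTrajectories:
    def _toy(self, rng, age_slope=0.0):
        subjects = [f"s{i}" for i in range(20)]
        groups = pd.Series(
            np.repeat(["X", "Y"], 10), index=subjects, name="group"
        )
        ages = rng.uniform(60, 80, 20)
        rows = []
        base_rows = []
        for sid, g, age in zip(subjects, groups, ages):
            slope = -1.0 if g == "X" else -0.2
            base = 28.0 + age_slope * age
            base_rows.append(
                {"subject_id": sid, "age": age, "sex": "F", "m": base}
            )
            for k in range(4):
                rows.append(
                    {"subject_id": sid, "months": 12.0 * k, "m": base + slope * k}
                )
        return pd.DataFrame(rows), pd.DataFrame(base_rows), groups

    def test_zero_covariate_effects_adjusted_equals_raw(self, rng):
        visits, baseline, groups = self._toy(rng, age_slope=0.0)
        adj = chz.adjusted_trajectories(visits, baseline, groups, "m", adjust=True)
        raw = chz.adjusted_trajectories(visits, baseline, groups, "m", adjust=False)
        merged = adj.merge(raw, on=["group", "year"], suffixes=("_a", "_r"))
        # residualization removes the common intercept; slopes/contrasts match
        diff = merged["mean_a"] - merged["mean_r"]
        assert diff.std() == pytest.approx(0.0, abs=1e-8)

    def test_planted_faster_decline_recovered(self, rng):
        visits, baseline, groups = self._toy(rng, age_slope=0.05)
        adj = chz.adjusted_trajectories(visits, baseline, groups, "m")
        x = adj[adj["group"] == "X"].sort_values("year")["mean"].to_numpy()
        y = adj[adj["group"] == "Y"].sort_values("year")["mean"].to_numpy()
        slope_x = np.polyfit(range(len(x)), x, 1)[0]
        slope_y = np.polyfit(range(len(y)), y, 1)[0]
        assert slope_x < slope_y  # X declines faster
        assert slope_x == pytest.approx(-1.0, abs=0.05)

    def test_constant_measure_flat(self, rng):
        visits, baseline, groups = self._toy(rng)
        visits["m"] = 5.0
        baseline["m"] = 5.0
        adj = chz.adjusted_trajectories(visits, baseline, groups, "m")
        assert adj["mean"].std() == pytest.approx(0.0, abs=1e-10)


class TestCrossCohortConsistency:
    def test_identical_vectors_r_one(self):
        r, p = chz.cross_cohort_consistency([1.0, -2.0, 0.5, 3.0], [1.0, -2.0, 0.5, 3.0])
        assert r == pytest.approx(1.0)

    def test_split_half_strong_effects_consistent(self, recovery_cohort):
        """Edgewise t-maps from two halves of one cohort correlate strongly."""
        from r2sn import discriminate as dsc, network as nw, pipeline as pl

        c = recovery_cohort
        dx = c.phenotypes.set_index("subject_id")["diagnosis"]
        norm = [nw.minmax_normalize(f) for f in c.feature_matrices]
        ret = nw.fit_feature_retention(
            [f for f in norm if dx[f.subject_id] == "NC"]
        )
        edf = pl.edge_matrix(norm, ret)
        grp = dx.reindex(edf.index)
        nc = edf[grp == "NC"].to_numpy()
        ad = edf[grp == "AD"].to_numpy()
        t1 = dsc.edgewise_ttest(nc[::2], ad[::2]).t_values
        t2 = dsc.edgewise_ttest(nc[1::2], ad[1::2]).t_values
        r, p = chz.cross_cohort_consistency(t1, t2)
        assert r > 0.5 and p < 0.001

    def test_independent_null_vectors_uncorrelated(self, rng):
        r, _ = chz.cross_cohort_consistency(rng.normal(size=500), rng.normal(size=500))
        assert abs(r) < 0.15

    def test_too_few_items_rejected(self):
        with pytest.raises(ParameterError):
            chz.cross_cohort_consistency([1.0, 2.0], [1.0, 2.0])
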