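"""Survival evaluation battery: time-dependent ROC, K-M/log-rank,
bootstrap nulls, robustness, multivariate adjustment, drug-response
surrogate classification and group comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mcgnet import evaluate, published, signature, simulate
from mcgnet.datatypes import Cohort, ValidationError

from conftest import toy_cohort, truth_signature


def binary_auc_oracle(scores, labels):
    """Exhaustive Mann-Whitney pair counting (ties 0.5)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestTimeDependentRoc:
    def test_constant_score_gives_auc_half(self):
        t = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        e = np.array([1, 1, 0, 1, 0, 0])
        roc = evaluate.time_dependent_roc(np.ones(6), t, e, 3.5)
        assert roc.auc == pytest.approx(0.5)

    def test_perfect_separation_gives_auc_one(self):
        t = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        e = np.ones(6, dtype=int)
        rs = np.array([9.0, 8.0, 7.0, 1.0, 2.0, 3.0])
        roc = evaluate.time_dependent_roc(rs, t, e, 5.0)
        assert roc.auc == 1.0
        # the Youden cutoff separates the groups perfectly
        assert 3.0 < roc.cutoff <= 7.0

    def test_uncensored_toy_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(2, size=8)
        e = np.ones(8, dtype=int)
        rs = rng.normal(size=8)
        horizon = float(np.median(t))
        roc = evaluate.time_dependent_roc(rs, t, e, horizon)
        labels = t <= horizon
        assert roc.auc == pytest.approx(binary_auc_oracle(rs, labels), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, planted_cohorts):
        _, valid, truth = planted_cohorts
        sig = published.macrophage_signature()
        rs = signature.apply_signature(sig, valid).scores.to_numpy()
        a = evaluate.time_dependent_roc(rs, valid.time, valid.event, 3.0).auc
        b = evaluate.time_dependent_roc(np.exp(rs / 3), valid.time, valid.event, 3.0).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_scikit_survival_ipcw_estimator(self, planted_cohorts):
        # independent implementation of the same cumulative/dynamic
        # KM-weighted estimator
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        _, valid, _ = planted_cohorts
        rs = signature.apply_signature(
            published.macrophage_signature(), valid
        ).scores.to_numpy()
        y = Surv.from_arrays(event=valid.event.astype(bool), time=valid.time)
        ref = cumulative_dynamic_auc(y, y, rs, [3.0])[0][0]
        ours = evaluate.time_dependent_roc(rs, valid.time, valid.event, 3.0).auc
        assert ours == pytest.approx(ref, abs=0.01)

    def test_no_cases_at_horizon_is_an_error(self):
        t = np.array([5.0, 6.0, 7.0])
        e = np.array([1, 1, 1])
        with pytest.raises(ValidationError, match="horizon"):
            evaluate.time_dependent_roc(np.array([1.0, 2.0, 3.0]), t, e, 1.0)

    def test_cutoff_attains_max_youden(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(2, size=50)
        e = rng.integers(0, 2, size=50)
        e[:5] = 1
        rs = rng.normal(size=50)
        roc = evaluate.time_dependent_roc(rs, t, e, float(np.median(t)))
        youden = roc.sensitivity + roc.specificity - 1.0
        i = int(np.argmax(youden))
        assert roc.cutoff == roc.thresholds[i]


class TestKmLogrank:
    def test_identical_event_time_multisets_give_zero_statistic(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        res = evaluate.km_logrank(t, e, g)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_six_patient_hand_worked_example(self):
        # observed-minus-expected computed by hand for the log-rank statistic:
        # group a dies at t=1,2,3; group b dies at t=4,5,6
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.ones(6, dtype=int)
        g = np.array(["a", "a", "a", "b", "b", "b"])
        res = evaluate.km_logrank(t, e, g)
        # hand computation: O_a = 3; E_a = 6/6*... sum of n_a/n at each death
        expected_a = 3 / 6 + 2 / 5 + 1 / 4  # deaths at t=1,2,3
        # t=4,5,6: no group-a patients at risk -> expectation 0
        var_terms = []
        at_risk = [(3, 3), (2, 3), (1, 3), (0, 3), (0, 2), (0, 1)]
        for na, nb in at_risk:
            n = na + nb
            if n > 1:
                var_terms.append(na * nb * (n - 1) / (n**2 * (n - 1)))
        chi2 = (3 - expected_a) ** 2 / sum(na * nb / (na + nb) ** 2 for na, nb in at_risk if na + nb > 1)
        assert res["chi2"] == pytest.approx(chi2, rel=1e-9)

    def test_empty_group_is_an_error(self):
        t = np.array([1.0, 2.0])
        e = np.array([1, 1])
        with pytest.raises(ValidationError):
            evaluate.km_logrank(t, e, np.array(["a", "a"]))

    def test_planted_signature_split_is_highly_significant(self, planted_cohorts):
        _, valid, truth = planted_cohorts
        rs = signature.apply_signature(truth_signature(truth), valid).scores
        roc = evaluate.time_dependent_roc(rs, valid.time, valid.event, 5.0)
        groups = evaluate.split_by_cutoff(rs, roc.cutoff)
        res = evaluate.km_logrank(valid.time, valid.event, groups)
        assert res["p"] < 1e-4


class TestRandomSignatureNull:
    def test_counting_conventions_when_observed_beats_all(self):
        res = evaluate.NullDistributionResult(
            observed_auc=0.9, null_aucs=np.full(200, 0.5),
            p_empirical=0.0, p_add_one=1 / 201, B=200, k=12, seed=0,
        )
        n_ge = int(np.sum(res.null_aucs >= res.observed_auc))
        assert n_ge / res.B == 0.0
        assert (1 + n_ge) / (res.B + 1) == pytest.approx(1 / 201)

    def test_universe_smaller_than_k_is_an_error(self, planted_cohorts):
        learn, valid, _ = planted_cohorts
        with pytest.raises(ValidationError):
            evaluate.random_signature_null(
                learn, valid, published.macrophage_signature(),
                k=12, B=5, gene_universe=["FANCA"], seed=0,
            )

    def test_planted_signal_is_never_matched_by_random_sets(self, planted_cohorts):
        learn, valid, truth = planted_cohorts
        sig = truth_signature(truth)
        res = evaluate.random_signature_null(
            learn, valid, sig, k=12, B=50, horizon=3.0, seed=4
        )
        assert res.observed_auc > 0.8
        assert res.p_empirical <= 0.02
        assert len(res.null_aucs) == 50


class TestRobustnessAndComparison:
    def test_full_fraction_replicates_equal_full_cohort_auc(self, planted_cohorts):
        _, valid, truth = planted_cohorts
        rs = signature.apply_signature(truth_signature(truth), valid).scores
        full = evaluate.time_dependent_roc(rs, valid.time, valid.event, 3.0).auc
        res = evaluate.robustness_subsample(
            valid, {"sig": rs}, fraction=1.0, B=2, horizons=(3.0,), seed=0
        )
        assert np.allclose(res.aucs["sig"][3.0], full)

    def test_strong_signature_beats_random_one(self, planted_cohorts):
        _, valid, truth = planted_cohorts
        rs = signature.apply_signature(truth_signature(truth), valid).scores
        rng = np.random.default_rng(0)
        random_rs = pd.Series(rng.normal(size=len(rs)), index=rs.index)
        res = evaluate.robustness_subsample(
            valid, {"planted": rs, "random": random_rs},
            fraction=0.5, B=30, horizons=(3.0,), seed=1,
        )
        assert res.wilcoxon_p["random"][3.0] < 0.01

    def test_identical_scores_bootstrap_p_is_half(self, planted_cohorts):
        _, valid, truth = planted_cohorts
        rs = signature.apply_signature(truth_signature(truth), valid).scores
        res = evaluate.compare_auc_bootstrap(
            rs, rs, valid.time, valid.event, 3.0, B=50, seed=3
        )
        assert res["p"] == pytest.approx(0.5)

    def test_informative_score_beats_noise(self, planted_cohorts):
        _, valid, truth = planted_cohorts
        rs = signature.apply_signature(truth_signature(truth), valid).scores
        rng = np.random.default_rng(1)
        noise = pd.Series(rng.normal(size=len(rs)), index=rs.index)
        sub = valid.expression.columns[:200]
        res = evaluate.compare_auc_bootstrap(
            rs.loc[sub], noise.loc[sub],
            valid.time[:200], valid.event[:200], 3.0, B=200, seed=5,
        )
        assert res["p"] < 0.01


class TestMultivariateCox:
    def test_planted_age_effect_recovered(self):
        # age >= 60 planted at HR 1.9; the multivariate fit including the
        # true risk score is correctly specified and recovers it
        truth = simulate.cohort_truth_preset()
        cohort, _ = simulate.simulate_cohort(truth, 690, seed=21)
        rs = signature.apply_signature(truth_signature(truth), cohort).scores
        res = evaluate.multivariate_cox(cohort, {"signature_1": rs})
        multi = {e.variable: e for e in res["multivariate"]}
        assert 1.6 <= multi["age_ge60"].hr <= 2.3
        assert multi["age_ge60"].p < 0.01
        assert multi["grade_high"].hr > 1.5

    def test_single_level_variable_is_an_error(self):
        cohort = toy_cohort(n=40, seed=8)
        cohort.clinical["grade"] = 1
        with pytest.raises(ValidationError, match="single level"):
            evaluate.multivariate_cox(cohort, {})

    def test_collinear_variables_error_names_the_pair(self):
        cohort = toy_cohort(n=40, seed=9)
        rs = pd.Series(
            (cohort.clinical["age"] >= 60).astype(float), index=cohort.clinical.index
        )
        with pytest.raises(ValidationError, match="age_ge60.*dup|dup.*age_ge60"):
            evaluate.multivariate_cox(cohort, {"dup": rs})

    def test_null_covariate_ci_covers_one(self):
        covered = 0
        for s in range(10):
            truth = simulate.CohortTruth(
                signature={}, beta_age60=0.0, beta_grade=0.0, n_genes=80
            )
            cohort, _ = simulate.simulate_cohort(truth, 300, seed=60 + s)
            rs = pd.Series(
                cohort.expression.loc["EGFR"].to_numpy(), index=cohort.clinical.index
            )
            res = evaluate.multivariate_cox(cohort, {"egfr_score": rs})
            e = {x.variable: x for x in res["univariate"]}["egfr_score"]
            covered += e.ci_low <= 1.0 <= e.ci_high
        assert covered >= 9


class TestStratifiedAndGroups:
    def test_constant_stratifier_reduces_to_single_stratum(self, planted_cohorts):
        _, valid, truth = planted_cohorts
        cohort = valid.subset(list(valid.expression.columns))
        cohort.clinical["radiotherapy"] = "yes"
        rs = signature.apply_signature(truth_signature(truth), cohort).scores
        strat = evaluate.stratified_km(cohort, "radiotherapy", rs, horizon=5.0)
        assert list(strat) == ["yes"]
        assert strat["yes"]["n"] == cohort.n_patients

    def test_signature_significant_in_both_grade_strata(self, planted_cohorts):
        _, valid, truth = planted_cohorts
        rs = signature.apply_signature(truth_signature(truth), valid).scores
        strat = evaluate.stratified_km(valid, "grade", rs, horizon=5.0)
        assert set(strat) == {"low_grade", "high_grade"}
        for s in strat.values():
            assert s["p"] < 0.01

    def test_four_stratifiers_give_eight_panels(self, planted_cohorts):
        _, valid, truth = planted_cohorts
        rs = signature.apply_signature(truth_signature(truth), valid).scores
        panels = []
        for strat_name in ("age", "grade", "pharmaceutical", "radiotherapy"):
            panels += list(evaluate.stratified_km(valid, strat_name, rs, horizon=5.0))
        assert len(panels) == 8

    def test_unknown_stratifier_is_an_error(self, planted_cohorts):
        _, valid, truth = planted_cohorts
        rs = signature.apply_signature(truth_signature(truth), valid).scores
        with pytest.raises(ValidationError):
            evaluate.stratified_km(valid, "shoe_size", rs, horizon=5.0)


class TestDrugResponse:
    def test_labels_follow_survival_status_at_horizon(self, planted_cohorts):
        _, valid, truth = planted_cohorts
        rs = signature.apply_signature(truth_signature(truth), valid).scores
        res = evaluate.drug_response_classification(valid, rs, horizon=3.0)
        ids = res["labels"].index
        sub = valid.clinical.loc[ids]
        dead = (sub["survival_time"] <= 3.0) & (sub["event"] == 1)
        assert (res["labels"][dead] == "resistant").all()
        assert (res["labels"][~dead] == "sensitive").all()
        assert res["km"]["p"] < 0.01
        assert res["auc"] > 0.7

    def test_single_class_labels_are_an_error(self, planted_cohorts):
        _, valid, truth = planted_cohorts
        cohort = valid.subset(list(valid.expression.columns))
        cohort.clinical["survival_time"] = 10.0  # everyone alive at 3y
        rs = signature.apply_signature(truth_signature(truth), cohort).scores
        with pytest.raises(ValidationError):
            evaluate.drug_response_classification(cohort, rs, horizon=3.0)


class TestGroupComparison:
    def test_identical_constant_groups_give_p_one(self):
        rs = pd.Series([1.0] * 6, index=[f"P{i}" for i in range(6)])
        ann = pd.Series(["a"] * 3 + ["b"] * 3, index=rs.index)
        table = evaluate.riskscore_group_comparison(rs, ann)
        assert table.loc[0, "p"] == 1.0

    def test_shifted_groups_are_significant(self):
        rng = np.random.default_rng(2)
        rs = pd.Series(
            np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)]),
            index=[f"P{i}" for i in range(100)],
        )
        ann = pd.Series(["a"] * 50 + ["b"] * 50, index=rs.index)
        table = evaluate.riskscore_group_comparison(rs, ann)
        assert table.loc[0, "p"] < 1e-6

    def test_four_level_annotation_gives_six_pairwise_tests(self, planted_cohorts):
        _, valid, truth = planted_cohorts
        rs = signature.apply_signature(truth_signature(truth), valid).scores
        table = evaluate.riskscore_group_comparison(rs, valid.clinical["subtype"])
        assert len(table) == 6

    def test_single_group_is_an_error(self):
        rs = pd.Series([1.0, 2.0, 3.0], index=["P1", "P2", "P3"])
        ann = pd.Series(["a", "a", "a"], index=rs.index)
        with pytest.raises(ValidationError):
            evaluate.riskscore_group_comparison(rs, ann)
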