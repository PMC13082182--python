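"""T2DM flags, HbA1c rules, logistic risk, Cox models, group comparisons."""
import numpy as np
import pandas as pd
import pytest

import hrphase as hp
from hrphase.outcomes import (build_survival_records, compare_groups,
                              cox_age_at_diagnosis, empirical_logit_by_decile,
                              filter_post_monitoring, flag_t2dm, logistic_risk,
                              max_hba1c_before_end)
from hrphase.phewas import ConditionOntology

from conftest import make_truth_cohort
from test_phewas import bfs_oracle, random_tree


class TestFlagT2DM:
    def test_deep_descendant_occurrence_flags(self):
        onto = ConditionOntology(pd.DataFrame(
            {"parent_id": [1, 2, 3, 4], "child_id": [2, 3, 4, 5]}))
        occ = pd.DataFrame({"participant_id": [7], "concept_id": [5]})
        flags = flag_t2dm(occ, onto, 1, np.array([7, 8]))
        assert flags.loc[7] == 1  # depth-4 descendant, unlimited closure
        assert flags.loc[8] == 0

    def test_no_occurrences_gives_zero(self):
        onto = ConditionOntology(hp.build_toy_ontology(2, 2))
        occ = pd.DataFrame(columns=["participant_id", "concept_id"])
        flags = flag_t2dm(occ, onto, 1, np.array([1, 2, 3]))
        assert (flags == 0).all()

    def test_matches_bfs_reachability_oracle(self):
        rng = np.random.default_rng(61)
        edges = random_tree(40, rng)
        onto = ConditionOntology(edges)
        pids = np.arange(1, 200)
        occ = pd.DataFrame({"participant_id": rng.choice(pids, 300),
                            "concept_id": rng.integers(0, 40, 300)})
        concept = 1
        members = set(bfs_oracle(edges, concept, None))
        expected = pd.Index(pids).isin(
            set(occ.loc[occ["concept_id"].isin(members), "participant_id"]))
        flags = flag_t2dm(occ, onto, concept, pids)
        np.testing.assert_array_equal(flags.to_numpy().astype(bool), expected)


class TestHbA1c:
    @staticmethod
    def _labs(rows):
        return pd.DataFrame(rows, columns=["participant_id", "date", "hba1c_pct"])

    def test_max_before_end_and_elevated(self):
        labs = self._labs([(1, "2022-01-01", 5.4), (1, "2022-01-15", 6.1),
                           (1, "2022-04-01", 7.0)])
        end = pd.Series({1: pd.Timestamp("2022-03-01")})
        out = max_hba1c_before_end(labs, end)
        assert out.loc[1, "max_hba1c"] == 6.1  # later 7.0 is past the end
        assert bool(out.loc[1, "elevated"])

    def test_out_of_range_value_excluded_participant_missing(self):
        labs = self._labs([(1, "2022-01-01", 0.5)])
        end = pd.Series({1: pd.Timestamp("2022-03-01")})
        out = max_hba1c_before_end(labs, end)
        assert 1 not in out.index

    def test_value_exactly_5_6_not_elevated(self):
        labs = self._labs([(1, "2022-01-01", 5.6)])
        end = pd.Series({1: pd.Timestamp("2022-03-01")})
        out = max_hba1c_before_end(labs, end)
        assert not bool(out.loc[1, "elevated"])

    def test_measurement_on_end_date_excluded_strict(self):
        labs = self._labs([(1, "2022-03-01", 6.0)])
        end = pd.Series({1: pd.Timestamp("2022-03-01")})
        out = max_hba1c_before_end(labs, end)
        assert 1 not in out.index

    def test_range_bounds_inclusive(self):
        labs = self._labs([(1, "2022-01-01", 1.0), (2, "2022-01-01", 30.0)])
        end = pd.Series({1: pd.Timestamp("2022-03-01"),
                         2: pd.Timestamp("2022-03-01")})
        out = max_hba1c_before_end(labs, end)
        assert set(out.index) == {1, 2}

    def test_model_cohort_equals_qualifying_participants(self):
        cfg = hp.SimConfig(n_participants=2000, seed=62, generate_hr=False,
                           hba1c_fraction=0.4)
        tables, cohort = make_truth_cohort(cfg)
        end = cohort.set_index("participant_id")["monitoring_end"]
        out = max_hba1c_before_end(tables.labs, end)
        # oracle: participants with >=1 in-range measurement strictly before end
        labs = tables.labs.copy()
        labs["end"] = end.reindex(labs["participant_id"]).to_numpy()
        ok = labs[(labs["hba1c_pct"] >= 1) & (labs["hba1c_pct"] <= 30)
                  & (pd.to_datetime(labs["date"]) < labs["end"])]
        assert set(out.index) == set(ok["participant_id"])


class TestLogisticRisk:
    def test_two_by_two_matches_cross_product_oracle(self):
        # exposed 20/100 cases, unexposed 10/100 -> OR (20*90)/(80*10)=2.25
        n1, n0 = 100, 100
        df = pd.DataFrame({
            "participant_id": np.arange(n1 + n0),
            "exposed": [1.0] * n1 + [0.0] * n0,
        })
        outcome = pd.Series([1] * 20 + [0] * 80 + [1] * 10 + [0] * 90,
                            index=df["participant_id"].to_numpy())
        res = logistic_risk(df, outcome, exposure="exposed")
        assert res.odds_ratio == pytest.approx(2.25, rel=1e-6)

    def test_null_exposure_or_near_one(self):
        cfg = hp.SimConfig(
            n_participants=15_000, seed=63, generate_hr=False,
            disease_specs=[hp.DiseaseSpec(concept_id=2, intercept=-1.8)])
        tables, cohort = make_truth_cohort(cfg)
        onto = ConditionOntology(tables.ontology_edges)
        flags = flag_t2dm(tables.conditions, onto, 2, cohort["participant_id"])
        res = logistic_risk(cohort, flags, exposure="phi")
        assert res.ci_low < 0.0 < res.ci_high

    def test_constant_outcome_flagged(self):
        cfg = hp.SimConfig(n_participants=200, seed=64, generate_hr=False)
        _, cohort = make_truth_cohort(cfg)
        outcome = pd.Series(0, index=cohort["participant_id"].to_numpy())
        res = logistic_risk(cohort, outcome, exposure="phi")
        assert not res.converged and res.flag == "constant_outcome"

    def test_empirical_logit_diagnostic_monotone_under_true_effect(self):
        rng = np.random.default_rng(65)
        n = 20_000
        x = rng.normal(0, 1.5, n)
        y = rng.random(n) < 1 / (1 + np.exp(-(-1.5 + 0.5 * x)))
        table = empirical_logit_by_decile(pd.Series(x), pd.Series(y.astype(int)))
        assert len(table) == 10
        slope = np.polyfit(table["mean_exposure"], table["empirical_logit"], 1)[0]
        assert slope == pytest.approx(0.5, abs=0.1)


class TestCox:
    def test_recovers_generative_log_hazard_ratio(self):
        rec = hp.simulate_survival_cohort(10_000, log_hr_per_hour=0.17, seed=66)
        rec = rec.rename(columns={"age": "age_at_event_or_censor"})
        cox = cox_age_at_diagnosis(rec, exposure="phi")
        assert abs(cox["log_hr"] - 0.17) < 3 * cox["se"]
        assert cox["n_events"] > 500

    def test_null_exposure_hr_near_one(self):
        rec = hp.simulate_survival_cohort(8000, log_hr_per_hour=0.0, seed=67)
        rec = rec.rename(columns={"age": "age_at_event_or_censor"})
        cox = cox_age_at_diagnosis(rec, exposure="phi")
        assert cox["hr_ci_low"] < 1.0 < cox["hr_ci_high"]

    def test_single_stratum_equals_unstratified(self):
        rec = hp.simulate_survival_cohort(3000, log_hr_per_hour=0.15, seed=68)
        rec = rec.rename(columns={"age": "age_at_event_or_censor"})
        rec["y_chromosome"] = True  # one stratum only
        strat = cox_age_at_diagnosis(rec, exposure="phi", check_ph=False)
        unstrat = cox_age_at_diagnosis(rec, exposure="phi", strata=None,
                                       check_ph=False)
        assert strat["log_hr"] == pytest.approx(unstrat["log_hr"], abs=1e-6)

    def test_invariant_to_age_origin_shift(self):
        rec = hp.simulate_survival_cohort(3000, log_hr_per_hour=0.15, seed=69)
        rec = rec.rename(columns={"age": "age_at_event_or_censor"})
        base = cox_age_at_diagnosis(rec, exposure="phi", check_ph=False)
        shifted = rec.copy()
        shifted["age_at_event_or_censor"] += 7.0
        after = cox_age_at_diagnosis(shifted, exposure="phi", check_ph=False)
        assert after["log_hr"] == pytest.approx(base["log_hr"], abs=1e-8)

    def test_no_events_raises(self):
        rec = hp.simulate_survival_cohort(500, log_hr_per_hour=0.1, seed=70)
        rec = rec.rename(columns={"age": "age_at_event_or_censor"})
        rec["event"] = False
        with pytest.raises(ValueError):
            cox_age_at_diagnosis(rec, exposure="phi")

    def test_post_monitoring_subgroup_consistent_effect(self):
        # time-homogeneous effect: subgroup estimate agrees within noise
        rec = hp.simulate_survival_cohort(20_000, log_hr_per_hour=0.17, seed=71)
        rec = rec.rename(columns={"age": "age_at_event_or_censor"})
        rec = rec.set_index("participant_id")
        full = cox_age_at_diagnosis(rec, exposure="phi", check_ph=False)
        start_age = pd.Series(40.0, index=rec.index)
        sub_rec = filter_post_monitoring(rec, start_age)
        sub = cox_age_at_diagnosis(sub_rec, exposure="phi", check_ph=False)
        assert abs(sub["log_hr"] - full["log_hr"]) < 3 * np.hypot(sub["se"], full["se"])

    def test_survival_records_event_age_is_earliest_occurrence(self):
        cfg = hp.SimConfig(n_participants=800, seed=72, generate_hr=False)
        tables, cohort = make_truth_cohort(cfg)
        onto = ConditionOntology(tables.ontology_edges)
        flags = flag_t2dm(tables.conditions, onto, 2, cohort["participant_id"])
        rec = build_survival_records(cohort, flags, tables.conditions, onto, 2)
        members = set(onto.descendants(2, max_depth=None))
        occ = tables.conditions[tables.conditions["concept_id"].isin(members)]
        first = occ.groupby("participant_id")["age_at_occurrence"].min()
        cases = rec[rec["event"]]
        np.testing.assert_allclose(cases["age_at_event_or_censor"],
                                   first.reindex(cases.index))


class TestCompareGroups:
    def test_identical_groups_d_zero(self):
        res = compare_groups([5.0] * 10, [5.0] * 10)
        assert res.cohens_d == 0.0
        assert res.p == 1.0
        assert res.flag == "zero_variance"

    def test_standardised_difference_of_one(self):
        rng = np.random.default_rng(73)
        x = rng.normal(0, 1, 10_000)
        y = rng.normal(1, 1, 10_000)
        res = compare_groups(x, y)
        assert res.cohens_d == pytest.approx(-1.0, abs=0.05)
        assert res.ci_low < res.cohens_d < res.ci_high
        assert res.p < 1e-10

    def test_sign_convention_earlier_vs_later(self):
        rng = np.random.default_rng(74)
        earlier = rng.normal(9.0, 1.5, 500)
        later = rng.normal(10.0, 1.5, 500)
        res = compare_groups(later, earlier)  # group1 - group2 > 0
        assert res.cohens_d > 0

    def test_mann_whitney_used_for_nonnormal_scale(self):
        rng = np.random.default_rng(75)
        res = compare_groups(rng.exponential(1, 100), rng.exponential(2, 100),
                             scale="nonnormal")
        assert res.test == "mann_whitney"

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
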