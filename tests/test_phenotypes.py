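"""Derived phenotypes: SNPD flags, SES grouping, Charlson index,
eligibility filters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cnvburden.phenotypes import (
    CHARLSON_WEIGHTS_DEFAULT,
    SNPD_PHENOTYPES,
    charlson_index,
    derive_snpd,
    eligibility_filter,
    ses_group,
    ses_groups,
)

CODE_MAP = {"F20": "SCZ", "F70": "ID", "G40": "EPI", "F31": "BD",
            "F32": "MDD", "F90": "CBD", "F84": "PDD"}


class TestSnpd:
    def test_schizophrenia_counts_as_snpd(self):
        out = derive_snpd({"s1": {"F20"}}, CODE_MAP)
        assert out.loc["s1", "SCZ"] and out.loc["s1", "any_snpd"]

    def test_depression_alone_is_not_snpd(self):
        out = derive_snpd({"s1": {"F32"}}, CODE_MAP)
        assert out.loc["s1", "MDD"] and not out.loc["s1", "any_snpd"]

    def test_no_diagnoses(self):
        out = derive_snpd({"s1": set()}, CODE_MAP)
        assert not out.loc["s1"].any()

    @given(st.sets(st.sampled_from(sorted(CODE_MAP)), max_size=7))
    def test_removing_depression_never_changes_any_snpd(self, codes):
        with_mdd = derive_snpd({"s": codes}, CODE_MAP)
        without = derive_snpd({"s": codes - {"F32"}}, CODE_MAP)
        assert with_mdd.loc["s", "any_snpd"] == without.loc["s", "any_snpd"]

    def test_unknown_target_phenotype_rejected(self):
        with pytest.raises(ValueError):
            derive_snpd({"s": set()}, {"X": "NOT_A_PHENOTYPE"})


class TestSesGroup:
    @pytest.mark.parametrize(
        "health, edu, income, expected",
        [
            (4, 2, 4, 1),   # poor health, low education, low income
            (2, 3, 6, 3),   # good health, upper secondary, good income
            (3, 2, 7, 2),   # fails group-1 income and group-3 education
            (3, 2, 5, 1),   # boundary: health 3, income 5 satisfy group 1
            (3, 3, 5, 3),   # same boundaries with upper-secondary education
        ],
    )
    def test_rule_evaluation(self, health, edu, income, expected):
        assert ses_group(health, edu, income) == expected

    def test_groups_partition_and_never_overlap(self):
        # education clauses alone force group1/group3 disjointness
        for h, e, i in itertools.product(range(1, 6), range(1, 5),
                                         range(1, 10)):
            g = ses_group(h, e, i)
            assert g in (1, 2, 3)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "subjective_health": rng.integers(1, 6, 200),
            "education_level": rng.integers(1, 5, 200),
            "household_income": rng.integers(1, 10, 200),
        })
        vec = ses_groups(df)
        scalar = [ses_group(h, e, i) for h, e, i in
                  df.itertuples(index=False)]
        assert (vec.to_numpy() == scalar).all()

    def test_missing_component_is_error(self):
        df = pd.DataFrame({"subjective_health": [3.0, np.nan],
                           "education_level": [2.0, 2.0],
                           "household_income": [4.0, 4.0]})
        with pytest.raises(ValueError, match="eligibility"):
            ses_groups(df)


class TestCharlson:
    def test_empty_is_zero(self):
        assert charlson_index([]) == 0

    def test_single_condition(self):
        assert charlson_index(["renal_disease"]) == 2

    def test_sum_of_weights(self):
        conds = ["myocardial_infarction", "dementia", "metastatic_solid_tumor"]
        assert charlson_index(conds) == 1 + 1 + 6

    def test_duplicates_counted_once(self):
        assert charlson_index(["dementia", "dementia"]) == 1

    @given(st.sets(st.sampled_from(sorted(CHARLSON_WEIGHTS_DEFAULT)),
                   max_size=8))
    def test_additive_and_permutation_invariant(self, conds):
        total = sum(CHARLSON_WEIGHTS_DEFAULT[c] for c in conds)
        assert charlson_index(conds) == total
        assert charlson_index(sorted(conds, reverse=True)) == total

    def test_custom_weight_map(self):
        assert charlson_index(["a", "b"], {"a": 3, "b": 4, "c": 9}) == 7
        with pytest.raises(ValueError):
            charlson_index(["a"], {"a": 0})


class TestEligibility:
    def _records(self):
        return pd.DataFrame({
            "age": [40, 70, 30, 50, 45],
            "student": [False, False, True, False, False],
            "education_status": ["completed", "completed", "completed",
                                 "other", "ongoing"],
            "education_level": [2.0, 3.0, 1.0, np.nan, 2.0],
            "education_years": [12.0, 16.0, 9.0, np.nan, 11.0],
            "household_income": [4.0, 6.0, np.nan, 5.0, 5.0],
            "subjective_health": [3.0, 2.0, 4.0, 3.0, np.nan],
            "follow_time": [10.0, 12.0, 8.0, 20.0, 15.0],
        })

    def test_education_excludes_other_and_ongoing(self):
        kept, report = eligibility_filter(self._records(), "education")
        assert len(kept) == 3
        reasons = dict(zip(report["reason"], report["n_excluded"]))
        assert reasons["education_ongoing"] == 1
        assert reasons["education_other"] == 1

    def test_ses_grouping_excludes_students_and_over_65(self):
        kept, report = eligibility_filter(self._records(), "ses_grouping")
        reasons = dict(zip(report["reason"], report["n_excluded"]))
        assert reasons["student"] == 1
        assert reasons["age_over_65"] == 1
        assert kept["age"].le(65).all()
        assert not kept[["subjective_health", "education_level",
                         "household_income"]].isna().any().any()

    def test_mortality_keeps_complete_followup(self):
        kept, _ = eligibility_filter(self._records(), "mortality")
        assert len(kept) == 5

    def test_counts_sum_to_input(self):
        rec = self._records()
        for analysis in ("education", "income", "health", "ses_grouping"):
            kept, report = eligibility_filter(rec, analysis)
            assert len(kept) + report["n_excluded"].sum() == len(rec)

    def test_unknown_analysis(self):
        with pytest.raises(ValueError):
            eligibility_filter(self._records(), "astrology")
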