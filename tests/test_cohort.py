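"""eGFR equation, index identification, eligibility branches, Charlson score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from msm_anemia import (
    apply_eligibility,
    build_cohort,
    charlson_score,
    compute_egfr,
    flag_subcohorts,
    identify_index,
)
from msm_anemia.codes import CCI_CODE_MAP

from conftest import make_checkup, make_enrollment


class TestComputeEgfr:
    def test_reference_values(self):
        assert compute_egfr(1.0, 50, "M") == pytest.approx(63.12, abs=0.005)
        assert compute_egfr(1.0, 50, "F") == pytest.approx(46.65, abs=0.005)

    def test_female_ratio_is_0739(self):
        m = compute_egfr(0.8, 63, "M")
        f = compute_egfr(0.8, 63, "F")
        assert f / m == pytest.approx(0.739, rel=1e-12)

    @given(scr=st.floats(0.3, 8.0), age=st.integers(18, 90))
    @settings(max_examples=50, deadline=None)
    def test_doubling_scr_more_than_halves_egfr(self, scr, age):
        assert compute_egfr(2 * scr, age, "M") < 0.5 * compute_egfr(scr, age, "M")

    def test_monotone_decreasing_in_scr_and_age(self):
        assert compute_egfr(1.2, 50, "M") < compute_egfr(1.0, 50, "M")
        assert compute_egfr(1.0, 60, "M") < compute_egfr(1.0, 50, "M")

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            compute_egfr(0.0, 50, "M")
        with pytest.raises(ValueError):
            compute_egfr(1.0, -1, "M")


class TestIdentifyIndex:
    def test_simple_pair(self):
        res = identify_index([("2010-01-01", 65), ("2011-01-01", 58)])
        assert res is not None
        assert res[1] == pd.Timestamp("2011-01-01")

    def test_first_low_record_does_not_qualify(self):
        res = identify_index(
            [("2010-01-01", 58), ("2011-01-01", 65), ("2012-01-01", 59)]
        )
        assert res == (pd.Timestamp("2011-01-01"), pd.Timestamp("2012-01-01"))

    def test_pair_beyond_two_years_rejected(self):
        assert identify_index([("2010-01-01", 65), ("2013-01-01", 58)]) is None

    def test_unsorted_input_raises(self):
        with pytest.raises(ValueError):
            identify_index([("2011-01-01", 65), ("2010-01-01", 58)])

    def test_requires_two_measurements(self):
        assert identify_index([("2010-01-01", 55)]) is None


def _fixture_tables():
    """Hand-constructed subjects exercising every eligibility branch."""
    checkups, enrollment = [], []
    scr_low_m1960 = 1.05   # eGFR ~59 for male born 1960 in 2011 (age 51)
    scr_high = 0.95        # eGFR ~66

    def subj(sid, dates_scr, hb=15.0, prot="-", **enr_kw):
        for d, s in dates_scr:
            checkups.append(make_checkup(sid, d, scr=s, hb=hb, proteinuria=prot))
        enrollment.append(make_enrollment(sid, **enr_kw))

    # 1: fully eligible
    subj(1, [("2010-06-01", scr_high), ("2011-06-01", scr_low_m1960),
             ("2012-06-01", scr_low_m1960)])
    # 2: death 1 year post-index -> retained despite short follow-up
    subj(2, [("2010-06-01", scr_high), ("2011-06-01", scr_low_m1960),
             ("2012-03-01", scr_low_m1960)],
         end="2012-06-01", death=1, death_date="2012-06-01")
    # 3: disenrolled 1 year post-index, alive -> insufficient follow-up
    subj(3, [("2010-06-01", scr_high), ("2011-06-01", scr_low_m1960),
             ("2012-03-01", scr_low_m1960)], end="2012-06-01")
    # 4: first-ever eGFR already < 60 -> no qualifying pair
    subj(4, [("2010-06-01", scr_low_m1960), ("2011-06-01", scr_low_m1960)])
    # 5: all eGFRs >= 60 -> never crosses
    subj(5, [("2010-06-01", scr_high), ("2011-06-01", scr_high)])
    # 6: qualifying drop but pair spans > 2 years
    subj(6, [("2010-06-01", scr_high), ("2013-06-01", scr_low_m1960),
             ("2014-06-01", scr_low_m1960)])
    # 7: no Hb at the index checkup
    for d, s in [("2010-06-01", scr_high), ("2011-06-01", scr_low_m1960),
                 ("2012-06-01", scr_low_m1960)]:
        checkups.append(make_checkup(7, d, scr=s,
                                     hb=np.nan if d == "2011-06-01" else 15.0))
    enrollment.append(make_enrollment(7))
    # 8: no proteinuria result at index
    subj(8, [("2010-06-01", scr_high), ("2011-06-01", scr_low_m1960),
             ("2012-06-01", scr_low_m1960)], prot=np.nan)
    # 9: lookback < 1 year
    subj(9, [("2010-10-01", scr_high), ("2011-06-01", scr_low_m1960),
             ("2012-06-01", scr_low_m1960)], start="2010-09-01")
    # 10: no post-index eGFR within 38 months (next measurement at 39 months)
    subj(10, [("2010-06-01", scr_high), ("2011-06-01", scr_low_m1960),
              ("2014-09-15", scr_low_m1960)])
    # 11: prior chronic dialysis
    subj(11, [("2010-06-01", scr_high), ("2011-06-01", scr_low_m1960),
              ("2012-06-01", scr_low_m1960)])
    # 12: under 18 at index
    subj(12, [("2010-06-01", scr_high), ("2011-06-01", 1.60),
              ("2012-06-01", 1.60)], birth_year=1995)

    claims = pd.DataFrame([
        {"subject_id": 11, "date": pd.Timestamp("2011-01-01"), "icd10": "N186",
         "record_type": "inpatient", "treatment_code": "chronic_dialysis"},
    ])
    return pd.DataFrame(checkups), claims, pd.DataFrame(enrollment)


class TestEligibility:
    def test_every_branch_labels_as_expected(self):
        ck, cl, enr = _fixture_tables()
        cohort, tally = build_cohort(ck, cl, enr)
        kept = set(cohort["subject_id"])
        assert kept == {1, 2}, f"retained {kept}"
        assert tally["insufficient_followup"] == 1      # subject 3
        assert tally["first_egfr_below_60"] == 1        # subject 4
        assert tally["no_egfr_below_60"] == 1           # subject 5
        assert tally["no_qualifying_pair"] == 1         # subject 6 (pair > 2 years)
        assert tally["missing_hb_at_index"] == 1        # subject 7
        assert tally["missing_proteinuria_at_index"] == 1  # subject 8
        assert tally["insufficient_lookback"] == 1      # subject 9
        assert tally["no_egfr_within_38_months"] == 1   # subject 10
        assert tally["prior_dialysis"] == 1             # subject 11
        assert tally["age_under_18"] == 1               # subject 12

    def test_tally_conserves_subjects(self):
        ck, cl, enr = _fixture_tables()
        cohort, tally = build_cohort(ck, cl, enr)
        n = tally.pop("n_input_subjects")
        retained = tally.pop("retained")
        assert retained + sum(tally.values()) == n

    def test_cohort_invariant_pre_ge_60_gt_index(self, cohort_small):
        cohort, tally = cohort_small
        assert (cohort["pre_index_egfr"] >= 60).all()
        assert (cohort["index_egfr"] < 60).all()
        assert (cohort["age_at_index"] >= 18).all()
        assert cohort["baseline_hb"].notna().all()

    def test_missing_enrollment_raises(self):
        ck, cl, enr = _fixture_tables()
        cand = pd.DataFrame({
            "subject_id": [999], "pre_index_date": [pd.Timestamp("2010-06-01")],
            "index_date": [pd.Timestamp("2011-06-01")],
            "pre_index_egfr": [66.0], "index_egfr": [59.0], "index_scr": [1.05],
        })
        with pytest.raises(ValueError, match="enrollment"):
            apply_eligibility(cand, ck, cl, enr, "2019-06-30")


class TestCharlson:
    def test_no_claims_scores_zero(self):
        assert charlson_score(pd.DataFrame(columns=["icd10"])) == 0

    def test_single_mi_scores_one(self):
        claims = pd.DataFrame({"icd10": ["I21.0"]})
        assert charlson_score(claims) == 1

    def test_diabetes_hierarchy_counts_complicated_only(self):
        claims = pd.DataFrame({"icd10": ["E119", "E112"]})
        assert charlson_score(claims) == 2  # complicated weight only
        assert charlson_score(pd.DataFrame({"icd10": ["E119"]})) == 1

    def test_metastatic_supersedes_localized(self):
        claims = pd.DataFrame({"icd10": ["C349", "C780"]})
        assert charlson_score(claims) == 6

    def test_categories_counted_once(self):
        claims = pd.DataFrame({"icd10": ["I21.0", "I22.1", "I252"]})
        assert charlson_score(claims) == 1

    def test_malformed_code_map_raises(self):
        with pytest.raises(ValueError):
            charlson_score(pd.DataFrame({"icd10": ["I21"]}),
                           code_map={"mi": {"codes": ["I21"]}})


class TestSubcohorts:
    def test_hba1c_threshold_inclusive(self):
        entry = {"index_date": "2011-06-01", "hba1c": 6.5}
        cv, dm = flag_subcohorts(entry, pd.DataFrame(
            columns=["subject_id", "date", "icd10", "treatment_code"]))
        assert dm and not cv

    def test_antidiabetic_rx_two_months_before_index(self):
        entry = {"index_date": "2011-06-01", "hba1c": 6.4}
        claims = pd.DataFrame([{
            "subject_id": 1, "date": pd.Timestamp("2011-04-01"),
            "icd10": "", "treatment_code": "other_antidiabetic",
        }])
        cv, dm = flag_subcohorts(entry, claims)
        assert dm

    def test_heart_failure_five_years_back_counts_for_cv_history(self):
        entry = {"index_date": "2011-06-01", "hba1c": 5.5}
        claims = pd.DataFrame([{
            "subject_id": 1, "date": pd.Timestamp("2006-06-01"),
            "icd10": "I50.9", "treatment_code": "",
        }])
        cv, dm = flag_subcohorts(entry, claims)
        assert cv and not dm

    def test_subcohorts_are_subsets_of_cohort(self, cohort_small):
        cohort, _ = cohort_small
        assert cohort["cv_history"].isin([True, False]).all()
        assert cohort["dm_baseline"].isin([True, False]).all()
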