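"""Cohort construction: index-date identification, eligibility, baseline covariates.

A subject enters the cohort at the first consecutive pair of eGFR values --
adjacent in the chronological measurement sequence and at most two years
apart -- where a value >= 60 mL/min/1.73 m2 is followed by one < 60; the
date of the second measurement is the index date.  Eligibility then requires
adult age, a one-year lookback, two years of follow-up (waived for the
deceased), hemoglobin and dipstick proteinuria at index, and no prior
dialysis/transplant, no eGFR < 6 at or before index, and at least one eGFR
within 38 months after index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codes as codes_mod
from .codes import CCI_HIERARCHY, CV_HISTORY_CATEGORIES, DIABETES_CATEGORIES
from .outcomes import AnemiaCriteria, classify_anemia, ANEMIA_TREATMENT_CODES

DAYS_PER_YEAR = 365.25

# Exclusion reasons in fixed precedence order (tallies are reproducible).
EXCLUSION_ORDER = (
    "first_egfr_below_60",
    "no_egfr_below_60",
    "no_qualifying_pair",
    "age_under_18",
    "insufficient_lookback",
    "insufficient_followup",
    "missing_hb_at_index",
    "missing_proteinuria_at_index",
    "prior_dialysis",
    "prior_transplant",
    "egfr_below_6_at_index",
    "no_egfr_within_38_months",
)


@dataclass(frozen=True)
class CohortParams:
    """Windows in whole days; '2 years' = 730, '38 months' = 1156 (30.43 d/month)."""

    pair_window_days: int = 730
    lookback_days: int = 365
    followup_days: int = 730
    post_index_egfr_window_days: int = 1156
    cci_window_days: int = 365          # comorbidity score: previous year
    cv_history_window_days: int = -1    # entire pre-index period
    malignancy_window_days: int = 730   # cancer/GI-bleed flags: previous 2 years
    dm_treatment_window_days: int = 90


def compute_egfr(scr, age, sex):
    """Three-variable Japanese eGFR equation: 194 * SCr^-1.094 * age^-0.287 (x0.739 if female)."""
    scr_a = np.asarray(scr, dtype=float)
    age_a = np.asarray(age, dtype=float)
    if np.any(scr_a <= 0):
        raise ValueError("scr must be positive")
    if np.any(age_a <= 0):
        raise ValueError("age must be positive")
    from .outcomes import _is_female

    female = _is_female(sex)
    out = 194.0 * scr_a ** -1.094 * age_a ** -0.287 * np.where(female, 0.739, 1.0)
    return float(out) if np.isscalar(scr) else out


def identify_index(egfr_series):
    """First adjacent (>=60, <60) pair within the 2-year window, for one subject.

    ``egfr_series``: sequence of (date, egfr), sorted ascending by date.
    Returns (pre_index_date, index_date) or None.
    """
    dates = pd.to_datetime(pd.Series([d for d, _ in egfr_series]))
    vals = np.asarray([v for _, v in egfr_series], dtype=float)
    if len(vals) < 2:
        return None
    if not dates.is_monotonic_increasing:
        raise ValueError("egfr_series must be sorted ascending by date")
    for i in range(1, len(vals)):
        gap = (dates.iloc[i] - dates.iloc[i - 1]).days
        if vals[i - 1] >= 60.0 and vals[i] < 60.0 and gap <= CohortParams().pair_window_days:
            return dates.iloc[i - 1], dates.iloc[i]
    return None


def _match_categories(claims_icd: pd.Series, code_map) -> pd.DataFrame:
    """Boolean matrix: claim row x CCI category (prefix match on dot-free codes)."""
    icd = codes_mod.normalize_icd(claims_icd)
    out = {}
    for cat, entry in code_map.items():
        prefixes = tuple(entry["codes"])
        out[cat] = icd.str.startswith(prefixes).to_numpy()
    return pd.DataFrame(out, index=claims_icd.index)


def charlson_score(claims, code_map=None) -> int:
    """CCI over a claims window: each matched category counted once,
    with hierarchy rules (complicated diabetes supersedes uncomplicated,
    metastatic supersedes localized cancer, severe supersedes mild liver)."""
    code_map = code_map or codes_mod.CCI_CODE_MAP
    for cat, entry in code_map.items():
        if "codes" not in entry or "weight" not in entry:
            raise ValueError(f"malformed code_map entry for {cat!r}")
    if len(claims) == 0:
        return 0
    hits = _match_categories(claims["icd10"], code_map).any(axis=0)
    score = 0
    for cat, present in hits.items():
        if not present:
            continue
        superseded_by = CCI_HIERARCHY.get(cat)
        if superseded_by and hits.get(superseded_by, False):
            continue
        score += int(code_map[cat]["weight"])
    return score


def flag_subcohorts(entry, claims, checkups=None,
                    code_map=None, params: CohortParams = CohortParams()):
    """(cv_history, dm_baseline) for one cohort entry.

    CV history: any of the four CCI cardiovascular categories during the
    entire pre-index period.  Baseline diabetes: CCI diabetes diagnosis, an
    antidiabetic prescription within 3 months pre-index, or HbA1c >= 6.5% at
    baseline.
    """
    code_map = code_map or codes_mod.CCI_CODE_MAP
    idx = pd.Timestamp(entry["index_date"])
    d = pd.to_datetime(claims["date"]) if len(claims) else pd.Series(dtype="datetime64[ns]")
    pre = claims[(d <= idx)] if len(claims) else claims
    cv_history = False
    dm_dx = False
    if len(pre):
        hits = _match_categories(pre["icd10"], code_map)
        cv_history = bool(hits[list(CV_HISTORY_CATEGORIES)].any().any())
        dm_dx = bool(hits[[c for c in DIABETES_CATEGORIES if c in hits]].any().any())
        dpre = pd.to_datetime(pre["date"])
        rx = pre[
            pre["treatment_code"].isin(codes_mod.ANTIDIABETIC_CODES)
            & (dpre >= idx - pd.Timedelta(days=params.dm_treatment_window_days))
        ]
        dm_rx = len(rx) > 0
    else:
        dm_rx = False
    hba1c = entry.get("hba1c", np.nan)
    dm_baseline = dm_dx or dm_rx or (pd.notna(hba1c) and hba1c >= 6.5)
    return bool(cv_history), bool(dm_baseline)


def _proteinuria_positive(grades: pd.Series) -> pd.Series:
    """Dipstick 1+ or above counts as proteinuria; '+-' is negative."""
    return grades.astype(str).isin(["1+", "2+", "3+"])


def apply_eligibility(candidates, checkups, claims, enrollment, study_end,
                      params: CohortParams = CohortParams(),
                      criteria: AnemiaCriteria | None = None,
                      code_map=None):
    """Filter index-date candidates to the analysis cohort.

    ``candidates``: DataFrame with subject_id, pre_index_date, index_date,
    pre_index_egfr, index_egfr, index_scr.  Returns (cohort, tally) where the
    tally counts each excluded subject once, under the first failing reason
    in ``EXCLUSION_ORDER``.
    """
    criteria = criteria or AnemiaCriteria.default()
    code_map = code_map or codes_mod.CCI_CODE_MAP
    study_end = pd.Timestamp(study_end)
    enr = enrollment.set_index("subject_id")
    missing = set(candidates["subject_id"]) - set(enr.index)
    if missing:
        raise ValueError(f"missing enrollment record for subjects {sorted(missing)[:5]}")

    c = candidates.copy()
    c["index_date"] = pd.to_datetime(c["index_date"])
    c = c.merge(
        enr[["sex", "birth_year", "start_date", "end_date", "death", "death_date"]],
        left_on="subject_id", right_index=True,
    )
    for col in ("start_date", "end_date", "death_date"):
        c[col] = pd.to_datetime(c[col])
    c["age_at_index"] = (
        c["index_date"] - pd.to_datetime(c["birth_year"].astype(str) + "-01-01")
    ).dt.days / DAYS_PER_YEAR
    c["follow_up_end"] = c["end_date"].clip(upper=study_end)
    c["death_date"] = c["death_date"].where(
        (c["death"] == 1) & (c["death_date"] <= c["follow_up_end"])
    )

    ck = checkups.copy()
    ck["date"] = pd.to_datetime(ck["date"])
    at_index = ck.merge(c[["subject_id", "index_date"]], on="subject_id")
    at_index = at_index[at_index["date"] == at_index["index_date"]]
    at_index = at_index.drop_duplicates("subject_id").set_index("subject_id")
    c["baseline_hb"] = c["subject_id"].map(at_index["hb"])
    c["proteinuria_grade"] = c["subject_id"].map(at_index["proteinuria_dipstick"])
    for col in ("bmi", "hba1c", "sbp", "smoker", "hct"):
        if col in at_index.columns:
            c[col] = c["subject_id"].map(at_index[col])

    # claims-derived lookups
    cl = claims.copy()
    cl["date"] = pd.to_datetime(cl["date"])
    cl = cl.merge(c[["subject_id", "index_date"]], on="subject_id", how="inner")
    pre_cl = cl[cl["date"] <= cl["index_date"]]
    dial = set(pre_cl.loc[pre_cl["treatment_code"] == "chronic_dialysis", "subject_id"])
    tx = set(pre_cl.loc[pre_cl["treatment_code"] == "kidney_transplant", "subject_id"])

    # any eGFR < 6 at or before index / any post-index eGFR within 38 months
    if "egfr" not in ck.columns:
        sex_m = ck["subject_id"].map(enr["sex"]).astype(str).str.upper()
        by_m = ck["subject_id"].map(enr["birth_year"]).astype(int)
        age_ck = (
            ck["date"] - pd.to_datetime(by_m.astype(str) + "-01-01")
        ).dt.days / DAYS_PER_YEAR
        ck = ck.assign(egfr=np.where(
            ck["scr"].notna() & (ck["scr"] > 0),
            194.0 * ck["scr"] ** -1.094 * np.maximum(age_ck, 18.0) ** -0.287
            * np.where(sex_m == "F", 0.739, 1.0),
            np.nan,
        ))
    ck2 = ck.merge(c[["subject_id", "index_date"]], on="subject_id")
    low6 = set(ck2.loc[(ck2["egfr"] < 6.0) & (ck2["date"] <= ck2["index_date"]),
                       "subject_id"])
    post_days = (ck2["date"] - ck2["index_date"]).dt.days
    has_post = set(
        ck2.loc[(post_days > 0)
                & (post_days <= params.post_index_egfr_window_days)
                & ck2["egfr"].notna(), "subject_id"]
    )

    fail = {}
    fail["age_under_18"] = c["age_at_index"] < 18.0
    fail["insufficient_lookback"] = (
        (c["index_date"] - c["start_date"]).dt.days < params.lookback_days
    )
    fu_days = (c["follow_up_end"] - c["index_date"]).dt.days
    fail["insufficient_followup"] = (fu_days < params.followup_days) & c[
        "death_date"
    ].isna()
    fail["missing_hb_at_index"] = c["baseline_hb"].isna()
    fail["missing_proteinuria_at_index"] = (
        c["proteinuria_grade"].isna() | (c["proteinuria_grade"].astype(str) == "nan")
    )
    fail["prior_dialysis"] = c["subject_id"].isin(dial)
    fail["prior_transplant"] = c["subject_id"].isin(tx)
    fail["egfr_below_6_at_index"] = c["subject_id"].isin(low6)
    fail["no_egfr_within_38_months"] = ~c["subject_id"].isin(has_post)

    tally = {}
    excluded = np.zeros(len(c), dtype=bool)
    for reason in EXCLUSION_ORDER:
        if reason not in fail:
            continue
        hit = fail[reason].to_numpy() & ~excluded
        tally[reason] = int(hit.sum())
        excluded |= hit

    kept = c[~excluded].copy()
    kept["proteinuria"] = _proteinuria_positive(kept["proteinuria_grade"])
    kept["baseline_anemia"] = classify_anemia(
        kept["baseline_hb"].to_numpy(), kept["age_at_index"].to_numpy(),
        kept["sex"].to_numpy(), criteria,
    )

    # Charlson score over the previous year; CV history over the entire
    # pre-index period; diabetes per diagnosis/treatment/HbA1c.
    kept_ids = set(kept["subject_id"])
    pre_kept = pre_cl[pre_cl["subject_id"].isin(kept_ids)]
    if len(pre_kept):
        hits = _match_categories(pre_kept["icd10"], code_map)
        hits["subject_id"] = pre_kept["subject_id"].to_numpy()
        days_before = (pre_kept["index_date"] - pre_kept["date"]).dt.days
        in_cci_win = (days_before.to_numpy() <= params.cci_window_days)
        cats = [cat for cat in code_map]
        win_hits = hits.loc[in_cci_win].groupby("subject_id")[cats].any()
        score = pd.Series(0, index=win_hits.index, dtype=int)
        for cat in cats:
            sup = CCI_HIERARCHY.get(cat)
            use = win_hits[cat]
            if sup is not None and sup in win_hits.columns:
                use = use & ~win_hits[sup]
            score += use.astype(int) * int(code_map[cat]["weight"])
        kept["cci_score"] = kept["subject_id"].map(score).fillna(0).astype(int)
        all_hits = hits.groupby("subject_id")[cats].any()
        cv_hist = all_hits[list(CV_HISTORY_CATEGORIES)].any(axis=1)
        dm_dx = all_hits[[cc for cc in DIABETES_CATEGORIES]].any(axis=1)
        kept["cv_history"] = kept["subject_id"].isin(cv_hist[cv_hist].index)
        dm_dx_flag = kept["subject_id"].isin(dm_dx[dm_dx].index)
        mal_win = (days_before.to_numpy() <= params.malignancy_window_days)
        mal = hits.loc[mal_win].groupby("subject_id")[["malignancy", "metastatic"]].any().any(axis=1) \
            if "malignancy" in hits.columns else pd.Series(dtype=bool)
        kept["cancer_2y"] = kept["subject_id"].isin(mal[mal].index)
    else:
        kept["cci_score"] = 0
        kept["cv_history"] = False
        dm_dx_flag = pd.Series(False, index=kept.index)
        kept["cancer_2y"] = False

    rx = pre_cl[
        pre_cl["treatment_code"].isin(codes_mod.ANTIDIABETIC_CODES)
        & ((pre_cl["index_date"] - pre_cl["date"]).dt.days
           <= params.dm_treatment_window_days)
    ]
    dm_rx_flag = kept["subject_id"].isin(set(rx["subject_id"]))
    kept["dm_baseline"] = (
        dm_dx_flag.to_numpy()
        | dm_rx_flag.to_numpy()
        | (kept["hba1c"].fillna(-1) >= 6.5).to_numpy()
    )

    # baseline anemia treatment (prescription within 3 months pre-index)
    atx = pre_cl[
        pre_cl["treatment_code"].isin(ANEMIA_TREATMENT_CODES)
        & ((pre_cl["index_date"] - pre_cl["date"]).dt.days <= 90)
    ]
    kept["baseline_anemia_treatment"] = kept["subject_id"].isin(set(atx["subject_id"]))

    cols = [
        "subject_id", "index_date", "pre_index_date", "pre_index_egfr",
        "index_egfr", "index_scr", "baseline_hb", "baseline_anemia",
        "proteinuria", "age_at_index", "sex", "cci_score", "cv_history",
        "dm_baseline", "cancer_2y", "baseline_anemia_treatment",
        "bmi", "hba1c", "sbp", "smoker", "hct",
        "follow_up_end", "death_date",
    ]
    cohort = kept[[col for col in cols if col in kept.columns]].reset_index(drop=True)
    assert (cohort["pre_index_egfr"] >= 60).all() and (cohort["index_egfr"] < 60).all()
    return cohort, tally


def build_cohort(checkups, claims, enrollment, study_end="2019-06-30",
                 params: CohortParams = CohortParams(),
                 criteria: AnemiaCriteria | None = None, code_map=None):
    """Full cohort construction from the three raw tables.

    Returns (cohort, tally); tally counts every subject present in the
    checkup table exactly once (retained subjects are counted under
    ``retained``).
    """
    ck = checkups.copy()
    ck["date"] = pd.to_datetime(ck["date"])
    enr = enrollment.set_index("subject_id")
    ck = ck[ck["subject_id"].isin(enr.index)]
    ck = ck.sort_values(["subject_id", "date"], kind="stable")
    ck["sex"] = ck["subject_id"].map(enr["sex"])
    ck["birth_year"] = ck["subject_id"].map(enr["birth_year"])
    age = (
        ck["date"] - pd.to_datetime(ck["birth_year"].astype(str) + "-01-01")
    ).dt.days / DAYS_PER_YEAR
    ck["egfr"] = np.where(
        ck["scr"].notna() & (ck["scr"] > 0),
        194.0 * ck["scr"] ** -1.094 * np.maximum(age, 18.0) ** -0.287
        * np.where(ck["sex"].astype(str).str.upper() == "F", 0.739, 1.0),
        np.nan,
    )

    meas = ck.dropna(subset=["egfr"])
    g = meas.groupby("subject_id")
    prev_egfr = g["egfr"].shift(1)
    prev_date = g["date"].shift(1)
    prev_scr = g["scr"].shift(1)
    qual = (
        (prev_egfr >= 60.0)
        & (meas["egfr"] < 60.0)
        & ((meas["date"] - prev_date).dt.days <= params.pair_window_days)
    )
    firsts = meas[qual].drop_duplicates("subject_id")
    candidates = pd.DataFrame({
        "subject_id": firsts["subject_id"].to_numpy(),
        "pre_index_date": prev_date[firsts.index].to_numpy(),
        "index_date": firsts["date"].to_numpy(),
        "pre_index_egfr": prev_egfr[firsts.index].to_numpy(),
        "index_egfr": firsts["egfr"].to_numpy(),
        "index_scr": firsts["scr"].to_numpy(),
    })

    # tally subjects that never form a qualifying pair
    all_ids = meas["subject_id"].unique()
    has_pair = set(candidates["subject_id"])
    no_pair = meas[~meas["subject_id"].isin(has_pair)]
    gg = no_pair.groupby("subject_id")["egfr"]
    first_low = gg.first() < 60.0
    all_high = gg.min() >= 60.0
    tally = {
        "first_egfr_below_60": int(first_low.sum()),
        "no_egfr_below_60": int((all_high & ~first_low).sum()),
        "no_qualifying_pair": int((~first_low & ~all_high).sum()),
    }
    cohort, tally2 = apply_eligibility(
        candidates, ck, claims, enrollment, study_end, params, criteria, code_map
    )
    tally.update(tally2)
    tally["retained"] = len(cohort)
    n_input = len(set(checkups["subject_id"]) & set(enr.index))
    tally["n_input_subjects"] = n_input
    return cohort, tally
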