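"""Anemia classification, composite endpoints, eGFR slopes.

Anemia is defined from age/sex-specific hemoglobin cutoffs (the renal-anemia
guideline bands <60, 60-69, >=70 years), evaluated at every annual checkup so
exposure status can switch on and off.  The composite renal endpoint is the
first of: >=30% eGFR reduction from the index value within 3 years, serum
creatinine doubling, progression to chronic dialysis, kidney transplantation,
or eGFR < 15 mL/min/1.73 m2.  The composite cardiovascular endpoint is the
first claim for unstable angina, myocardial infarction, heart failure, or a
cerebrovascular event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25
RENAL_3Y_DAYS = 1095  # 3 x 365: window for the 30%-reduction component

ANEMIA_TREATMENT_CODES = ("esa", "oral_iron", "iv_iron", "rbc_transfusion")
RENAL_CLAIM_CODES = ("chronic_dialysis", "kidney_transplant")


@dataclass(frozen=True)
class AnemiaCriteria:
    """Hemoglobin cutoffs (g/dL) by sex and age band; anemia <=> hb strictly below."""

    male: Tuple[float, float, float] = (13.5, 12.0, 11.0)
    female: Tuple[float, float, float] = (11.5, 10.5, 10.5)
    age_breaks: Tuple[float, float] = (60.0, 70.0)

    @classmethod
    def default(cls) -> "AnemiaCriteria":
        return cls()

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnemiaCriteria":
        return cls(
            male=tuple(d["male"]),
            female=tuple(d["female"]),
            age_breaks=tuple(d.get("age_breaks", (60.0, 70.0))),
        )

    def __post_init__(self):
        if any(v <= 0 for v in self.male + self.female):
            raise ValueError("cutoffs must be positive")
        if any(m < f for m, f in zip(self.male, self.female)):
            raise ValueError("male cutoffs must be >= female cutoffs per band")

    def cutoff_array(self, age, female):
        """Vectorized cutoff lookup; `female` boolean, `age` in years."""
        age = np.asarray(age, dtype=float)
        female = np.asarray(female, dtype=bool)
        band = np.digitize(age, self.age_breaks)  # 0: <60, 1: 60-69, 2: >=70
        m = np.asarray(self.male, dtype=float)[band]
        f = np.asarray(self.female, dtype=float)[band]
        return np.where(female, f, m)


def _is_female(sex) -> np.ndarray:
    s = np.asarray(sex)
    if s.dtype.kind in "US" or s.dtype == object:
        return np.char.upper(s.astype(str)) == "F"
    return s.astype(bool)


def classify_anemia(hb, age, sex, criteria: Optional[AnemiaCriteria] = None):
    """True iff hb is strictly below the (sex, age-band) cutoff.

    Accepts scalars or arrays; missing hb raises for scalars and propagates
    NaN -> <NA> handling upstream for arrays (caller decides policy).
    """
    criteria = criteria or AnemiaCriteria.default()
    scalar = np.isscalar(hb)
    hb_arr = np.asarray(hb, dtype=float)
    if scalar and np.isnan(hb_arr):
        raise ValueError("hb is missing; classify_anemia requires a value")
    cut = criteria.cutoff_array(age, _is_female(sex))
    out = hb_arr < cut
    return bool(out) if scalar else out


def build_exposure_panel(dates, hb, age_at_index, sex, criteria=None):
    """Per-checkup anemia sequence A_0..A_K for one subject.

    ``dates`` are checkup dates (index first, sorted); ``hb`` aligned values
    (NaN where missing -- left NaN here, resolved by the imputation policy of
    the weights module).  Age is advanced from ``age_at_index`` by calendar
    time, so band crossings alone can flip status.
    """
    criteria = criteria or AnemiaCriteria.default()
    dates = pd.to_datetime(pd.Series(list(dates)))
    if len(dates) == 0:
        return pd.DataFrame(columns=["k", "date", "hb", "anemia"])
    if dates.iloc[0] is pd.NaT or pd.isna(hb[0] if len(hb) else np.nan):
        raise ValueError("baseline hb must be present (A_0 always defined)")
    days = (dates - dates.iloc[0]).dt.days.to_numpy()
    age = np.asarray(age_at_index, dtype=float) + days / DAYS_PER_YEAR
    hb_arr = np.asarray(hb, dtype=float)
    cut = criteria.cutoff_array(age, np.repeat(_is_female(sex), len(days)))
    anemia = np.where(np.isnan(hb_arr), np.nan, (hb_arr < cut).astype(float))
    return pd.DataFrame(
        {"k": np.arange(len(days)), "date": dates, "day": days,
         "hb": hb_arr, "anemia": anemia}
    )


def _first_or_nat(dates: pd.Series):
    return dates.min() if len(dates) else pd.NaT


def derive_renal_outcome(entry, checkups, claims) -> dict:
    """Composite renal endpoint for one cohort entry.

    ``entry`` needs index_date, index_egfr, index_scr, follow_up_end;
    ``checkups`` the subject's post-index rows with egfr/scr; ``claims`` the
    subject's claims.  Event time = earliest firing component.
    """
    idx = pd.Timestamp(entry["index_date"])
    end = pd.Timestamp(entry["follow_up_end"])
    ck = checkups[(pd.to_datetime(checkups["date"]) > idx)
                  & (pd.to_datetime(checkups["date"]) <= end)]
    if ck.empty and claims.empty:
        raise ValueError("no post-index measurements for subject "
                         f"{entry.get('subject_id')}")
    d = pd.to_datetime(ck["date"])
    comp = {}
    comp["egfr_30pct_3y"] = _first_or_nat(
        d[(ck["egfr"] <= 0.70 * entry["index_egfr"])
          & ((d - idx).dt.days <= RENAL_3Y_DAYS)]
    )
    comp["scr_doubling"] = _first_or_nat(d[ck["scr"] >= 2.0 * entry["index_scr"]])
    comp["egfr_lt15"] = _first_or_nat(d[ck["egfr"] < 15.0])
    cl = claims[claims["treatment_code"].isin(RENAL_CLAIM_CODES)]
    cd = pd.to_datetime(cl["date"])
    cl = cl[(cd > idx) & (cd <= end)]
    comp["dialysis_or_transplant"] = _first_or_nat(pd.to_datetime(cl["date"]))
    valid = {kk: v for kk, v in comp.items() if pd.notna(v)}
    if valid:
        component = min(valid, key=valid.get)
        t = (valid[component] - idx).days
        return {"outcome": "renal", "event": 1, "time_days": int(t),
                "component": component}
    return {"outcome": "renal", "event": 0, "time_days": int((end - idx).days),
            "component": ""}


def derive_cv_outcome(entry, claims, code_map) -> dict:
    """First qualifying cardiovascular claim; fatal if death follows within 30 days."""
    idx = pd.Timestamp(entry["index_date"])
    end = pd.Timestamp(entry["follow_up_end"])
    prefixes = tuple(p for cat in code_map.values() for p in cat)
    icd = claims["icd10"].astype(str).str.replace(".", "", regex=False)
    hit = claims[icd.str.startswith(prefixes)
                 & (pd.to_datetime(claims["date"]) > idx)
                 & (pd.to_datetime(claims["date"]) <= end)]
    t0 = _first_or_nat(pd.to_datetime(hit["date"]))
    if pd.notna(t0):
        death = entry.get("death_date")
        fatal = pd.notna(death) and 0 <= (pd.Timestamp(death) - t0).days <= 30
        return {"outcome": "cv", "event": 1, "time_days": int((t0 - idx).days),
                "component": "fatal" if fatal else "nonfatal"}
    return {"outcome": "cv", "event": 0, "time_days": int((end - idx).days),
            "component": ""}


def derive_death_outcome(entry) -> dict:
    idx = pd.Timestamp(entry["index_date"])
    end = pd.Timestamp(entry["follow_up_end"])
    death = entry.get("death_date")
    if pd.notna(death):
        return {"outcome": "death", "event": 1,
                "time_days": int((pd.Timestamp(death) - idx).days), "component": ""}
    return {"outcome": "death", "event": 0, "time_days": int((end - idx).days),
            "component": ""}


def derive_outcomes(cohort, checkups, claims, cv_code_map) -> pd.DataFrame:
    """Vectorized endpoint derivation for the whole cohort.

    Returns one row per subject per outcome: subject_id, outcome, event,
    time_days, component.
    """
    coh = cohort.set_index("subject_id")
    ck = checkups.merge(
        coh[["index_date", "follow_up_end", "index_egfr", "index_scr"]],
        left_on="subject_id", right_index=True, how="inner",
    )
    ck["date"] = pd.to_datetime(ck["date"])
    ck = ck[(ck["date"] > ck["index_date"]) & (ck["date"] <= ck["follow_up_end"])]
    dd = (ck["date"] - ck["index_date"]).dt.days

    def first_day(mask):
        sub = ck[mask]
        days = (sub["date"] - sub["index_date"]).dt.days
        return days.groupby(sub["subject_id"]).min()

    comp_days = {
        "egfr_30pct_3y": first_day(
            (ck["egfr"] <= 0.70 * ck["index_egfr"]) & (dd <= RENAL_3Y_DAYS)
        ),
        "scr_doubling": first_day(ck["scr"] >= 2.0 * ck["index_scr"]),
        "egfr_lt15": first_day(ck["egfr"] < 15.0),
    }
    cl = claims.merge(
        coh[["index_date", "follow_up_end"]],
        left_on="subject_id", right_index=True, how="inner",
    )
    cl["date"] = pd.to_datetime(cl["date"])
    cl = cl[(cl["date"] > cl["index_date"]) & (cl["date"] <= cl["follow_up_end"])]
    rcl = cl[cl["treatment_code"].isin(RENAL_CLAIM_CODES)]
    comp_days["dialysis_or_transplant"] = (
        (rcl["date"] - rcl["index_date"]).dt.days.groupby(rcl["subject_id"]).min()
    )

    comp = pd.DataFrame(comp_days).reindex(coh.index)
    renal_day = comp.min(axis=1)
    renal_comp = comp.fillna(np.inf).idxmin(axis=1).where(renal_day.notna(), "")
    fu = (coh["follow_up_end"] - coh["index_date"]).dt.days.astype(float)

    prefixes = tuple(p for cat in cv_code_map.values() for p in cat)
    icd = cl["icd10"].astype(str).str.replace(".", "", regex=False)
    cv_hit = cl[icd.str.startswith(prefixes)]
    cv_day = (
        (cv_hit["date"] - cv_hit["index_date"]).dt.days
        .groupby(cv_hit["subject_id"]).min().reindex(coh.index)
    )
    death_day = (
        (pd.to_datetime(coh["death_date"]) - coh["index_date"]).dt.days.astype(float)
    )
    cv_fatal = (death_day - cv_day).between(0, 30)

    frames = []
    for name, day, component in [
        ("renal", renal_day, renal_comp),
        ("cv", cv_day, np.where(cv_day.notna(),
                                np.where(cv_fatal, "fatal", "nonfatal"), "")),
        ("death", death_day, ""),
    ]:
        ev = day.notna() & (day <= fu)
        frames.append(pd.DataFrame({
            "subject_id": coh.index,
            "outcome": name,
            "event": ev.astype(int).to_numpy(),
            "time_days": np.where(ev, day, fu).astype(int),
            "component": np.where(ev, component, ""),
        }))
    return pd.concat(frames, ignore_index=True)


def egfr_slope(days, egfr) -> float:
    """OLS slope of eGFR on time, in mL/min/1.73 m2 per year."""
    t = np.asarray(days, dtype=float) / DAYS_PER_YEAR
    y = np.asarray(egfr, dtype=float)
    ok = ~(np.isnan(t) | np.isnan(y))
    t, y = t[ok], y[ok]
    if len(t) < 2:
        raise ValueError("egfr_slope requires >= 2 measurements")
    if np.ptp(t) == 0:
        raise ValueError("egfr_slope requires non-zero time spread")
    tc = t - t.mean()
    return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))


def egfr_slopes(checkups, cohort) -> pd.Series:
    """Per-subject eGFR slopes over the index + post-index measurements."""
    ck = checkups.merge(cohort[["subject_id", "index_date", "follow_up_end"]],
                        on="subject_id")
    ck["date"] = pd.to_datetime(ck["date"])
    ck = ck[(ck["date"] >= ck["index_date"]) & (ck["date"] <= ck["follow_up_end"])]
    ck = ck.dropna(subset=["egfr"])
    t = (ck["date"] - ck["index_date"]).dt.days / DAYS_PER_YEAR
    g = ck.assign(t=t).groupby("subject_id")
    n = g["t"].transform("count")
    sub = ck.assign(t=t)[n >= 2]
    g = sub.groupby("subject_id")
    tm = g["t"].transform("mean")
    ym = g["egfr"].transform("mean")
    num = ((sub["t"] - tm) * (sub["egfr"] - ym)).groupby(sub["subject_id"]).sum()
    den = ((sub["t"] - tm) ** 2).groupby(sub["subject_id"]).sum()
    return (num / den).rename("egfr_slope")


def slope_to_hazard(delta_slope: float, reference: Tuple[float, float] = (0.75, 0.27)
                    ) -> float:
    """Translate an eGFR-slope difference into a percent hazard change.

    Uses proportional log-hazard scaling anchored at a reference mapping: a
    slope benefit of ``reference[0]`` mL/min/1.73 m2/year corresponds to a
    ``reference[1]`` fractional hazard reduction.  A slope deficit (negative
    delta) therefore yields a positive percent hazard increase:
    ``(1/(1-r))**(-delta/s) - 1``, in percent.
    """
    s, r = reference
    return float(((1.0 / (1.0 - r)) ** (-delta_slope / s) - 1.0) * 100.0)
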