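"""Person-period construction: one row per subject per checkup interval.

Exposure can only be observed at annual checkups, so periods run from each
post-index checkup (the index checkup is period 0) to the next one; the
final period extends to the end of follow-up.  Event/censoring times stay in
days inside the final period when an outcome is attached.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .outcomes import AnemiaCriteria, ANEMIA_TREATMENT_CODES, DAYS_PER_YEAR


def build_person_periods(cohort, checkups, claims=None,
                         criteria: AnemiaCriteria | None = None,
                         treatment_window_days: int = 365) -> pd.DataFrame:
    """Covariate panel for the weight models and the marginal structural Cox.

    Columns: subject_id, k, date, start_day, end_day, egfr, hb, anemia (may
    be NaN where Hb is missing; resolve with ``simple_impute`` before weight
    fitting), anemia_lag / egfr_lag / treatment_lag (0 / baseline at k=0),
    anemia_cum, anemia_treatment, plus baseline age/sex/female carried on
    every row.
    """
    criteria = criteria or AnemiaCriteria.default()
    coh = cohort.set_index("subject_id")
    ck = checkups.merge(
        coh[["index_date", "follow_up_end", "age_at_index", "sex"]],
        left_on="subject_id", right_index=True, how="inner",
    ).copy()
    ck["date"] = pd.to_datetime(ck["date"])
    ck = ck[(ck["date"] >= ck["index_date"]) & (ck["date"] <= ck["follow_up_end"])]
    ck = ck.sort_values(["subject_id", "date"], kind="stable")
    ck["k"] = ck.groupby("subject_id").cumcount()
    ck["start_day"] = (ck["date"] - ck["index_date"]).dt.days
    fu_days = (ck["follow_up_end"] - ck["index_date"]).dt.days
    nxt = ck.groupby("subject_id")["start_day"].shift(-1)
    ck["end_day"] = nxt.fillna(fu_days).astype(float)
    ck = ck[ck["end_day"] > ck["start_day"]]

    age = ck["age_at_index"] + ck["start_day"] / DAYS_PER_YEAR
    female = ck["sex"].astype(str).str.upper() == "F"
    cut = criteria.cutoff_array(age.to_numpy(), female.to_numpy())
    hb = ck["hb"].to_numpy(dtype=float)
    ck["anemia"] = np.where(np.isnan(hb), np.nan, (hb < cut).astype(float))
    ck["age"] = age
    ck["female"] = female.astype(int)

    # anemia treatment: any qualifying pharmacy claim in the window before the checkup
    ck["anemia_treatment"] = 0.0
    if claims is not None and len(claims):
        tr = claims[claims["treatment_code"].isin(ANEMIA_TREATMENT_CODES)].copy()
        if len(tr):
            tr["date"] = pd.to_datetime(tr["date"])
            m = ck[["subject_id", "k", "date"]].merge(
                tr[["subject_id", "date"]].rename(columns={"date": "tr_date"}),
                on="subject_id",
            )
            m = m[
                (m["tr_date"] <= m["date"])
                & (m["tr_date"] > m["date"] - pd.Timedelta(days=treatment_window_days))
            ]
            treated = set(zip(m["subject_id"], m["k"]))
            if treated:
                key = list(zip(ck["subject_id"], ck["k"]))
                ck["anemia_treatment"] = np.array(
                    [1.0 if t in treated else 0.0 for t in key]
                )

    g = ck.groupby("subject_id", sort=False)
    ck["anemia_lag"] = g["anemia"].shift(1).fillna(0.0)  # A_{-1} := 0
    ck["egfr_lag"] = g["egfr"].shift(1)
    ck["egfr_lag"] = ck["egfr_lag"].fillna(ck["egfr"])
    ck["treatment_lag"] = g["anemia_treatment"].shift(1).fillna(0.0)
    ck["anemia_cum"] = g["anemia"].cumsum().fillna(0.0) - ck["anemia"].fillna(0.0)

    keep = ["subject_id", "k", "date", "start_day", "end_day", "egfr", "hb",
            "anemia", "anemia_lag", "anemia_cum", "egfr_lag",
            "anemia_treatment", "treatment_lag", "age", "female"]
    extra = [c for c in ("hba1c", "smoker", "bmi", "sbp", "proteinuria_dipstick")
             if c in ck.columns]
    return ck[keep + extra].reset_index(drop=True)


def attach_outcome(pp, outcome_table, outcome: str = "renal") -> pd.DataFrame:
    """Truncate the panel at each subject's event/censoring time for one outcome.

    Adds ``stop_day`` (period end capped at the outcome time) and ``event``
    (1 on the period containing an observed event); drops periods starting at
    or after the outcome time.
    """
    ev = outcome_table[outcome_table["outcome"] == outcome].set_index("subject_id")
    out = pp.copy()
    out["T"] = out["subject_id"].map(ev["time_days"]).astype(float)
    out["is_event"] = out["subject_id"].map(ev["event"]).astype(float)
    out = out[out["start_day"] < out["T"]]
    out["stop_day"] = np.minimum(out["end_day"], out["T"])
    out["event"] = (
        (out["is_event"] == 1) & (out["T"] <= out["end_day"])
    ).astype(int)
    return out.drop(columns=["T", "is_event"])
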