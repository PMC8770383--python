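import numpy as np
import pandas as pd
import pytest

from msm_anemia import SimulationConfig, simulate_cohort, build_cohort
from msm_anemia.codes import CV_EVENT_CODE_MAP
from msm_anemia.outcomes import derive_outcomes
from msm_anemia.panel import build_person_periods
from msm_anemia.report import _with_egfr


@pytest.fixture(scope="session")
def sim_small():
    """A small but complete synthetic dataset (shared, read-only)."""
    cfg = SimulationConfig(n_subjects=1200, seed=42)
    checkups, claims, enrollment, truth = simulate_cohort(cfg)
    return {"config": cfg, "checkups": checkups, "claims": claims,
            "enrollment": enrollment, "truth": truth}


@pytest.fixture(scope="session")
def cohort_small(sim_small):
    cohort, tally = build_cohort(
        sim_small["checkups"], sim_small["claims"], sim_small["enrollment"]
    )
    cohort = cohort.copy()
    cohort["female"] = (cohort["sex"].astype(str).str.upper() == "F").astype(int)
    return cohort, tally


@pytest.fixture(scope="session")
def analysis_small(sim_small, cohort_small):
    """Cohort + outcomes + person-period panel, ready for weight/Cox fitting."""
    cohort, _ = cohort_small
    cke = _with_egfr(sim_small["checkups"], sim_small["enrollment"])
    outcomes = derive_outcomes(cohort, cke, sim_small["claims"], CV_EVENT_CODE_MAP)
    pp = build_person_periods(cohort, cke, sim_small["claims"])
    return {"cohort": cohort, "checkups": cke, "claims": sim_small["claims"],
            "outcomes": outcomes, "pp": pp}


def make_enrollment(subject_id, sex="M", birth_year=1960,
                    start="2007-01-01", end="2019-06-30",
                    death=0, death_date=None):
    return {
        "subject_id": subject_id, "sex": sex, "birth_year": birth_year,
        "start_date": pd.Timestamp(start), "end_date": pd.Timestamp(end),
        "death": death,
        "death_date": pd.Timestamp(death_date) if death_date else pd.NaT,
    }


def make_checkup(subject_id, date, scr=1.0, hb=15.0, proteinuria="-", **kw):
    row = {
        "subject_id": subject_id, "date": pd.Timestamp(date), "scr": scr,
        "hb": hb, "hct": 3 * hb if hb is not None else np.nan, "bmi": 23.0,
        "hba1c": 5.5, "sbp": 120.0, "proteinuria_dipstick": proteinuria,
        "smoker": 0,
    }
    row.update(kw)
    return row
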