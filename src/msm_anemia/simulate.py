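"""Synthetic JMDC-like longitudinal cohort generator with known causal structure.

The generator emits the three raw tables the pipeline consumes (annual
checkups, claims, enrollment) for a population entering stage-3 renal
impairment, plus a hidden truth table for test assertions.  The causal
structure is the one a marginal structural model is designed for:

* a latent per-subject susceptibility ``U`` drives both eGFR decline and the
  event hazards (scaled by ``confounding_strength``);
* anemia at period ``k`` depends on the *previous* period's eGFR, anemia
  status, and anemia treatment;
* anemia treatment at ``k`` depends on anemia at ``k - 1``;
* eGFR at ``k`` is pushed down by anemia at ``k - 1`` (the slope
  acceleration) and by ``U``;
* event hazards are piecewise-constant within annual intervals and depend on
  the *current* anemia status through the configured true log hazard ratios.

Because observed eGFR is a function of latent susceptibility *and* of past
exposure, a time-dependent Cox model that adjusts for current covariates is
biased for the causal hazard ratio, while inverse-probability weighting on
the (correctly specified) exposure model recovers it.  Renal and
cardiovascular events are surfaced as claims (chronic dialysis / transplant
codes, CV diagnosis codes) so the downstream outcome-derivation stage picks
them up; deaths land in the enrollment table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .outcomes import AnemiaCriteria

OUTCOMES = ("renal", "cv", "death")

# Claims vocabulary understood by the cohort/outcome modules.
CV_EVENT_CODES = ("I200", "I219", "I509", "I639")
DIALYSIS_CODE = "N186"
TRANSPLANT_CODE = "Z940"

DAYS_PER_YEAR = 365.25


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the population the pipeline targets: ~73% male, median
    age 52, index eGFR just under 60 mL/min/1.73 m2, 4.2% baseline anemia
    prevalence, annual checkups, and per-outcome hazard ratios of anemia
    near the magnitudes reported for this kind of cohort (renal ~2.6,
    cardiovascular ~1.6, mortality ~2.8).  ``egfr_drift`` is the mean annual
    eGFR change and its anemia-dependent acceleration (mL/min/1.73 m2 per
    year); the acceleration default of -0.7 matches the observed slope
    difference between anemic and non-anemic subjects.
    """

    n_subjects: int = 5000
    n_years: int = 6
    seed: int = 0
    true_log_hr: Mapping[str, float] = field(
        default_factory=lambda: {
            "renal": float(np.log(2.6)),
            "cv": float(np.log(1.6)),
            "death": float(np.log(2.8)),
        }
    )
    confounding_strength: float = 1.0
    baseline_anemia_prob: float = 0.042
    egfr_drift: tuple = (-1.0, -0.7)
    censoring_rate: float = 0.08
    missingness_rate: float = 0.0
    # Annual baseline hazards (events per person-year in the unexposed,
    # average-susceptibility stratum).
    base_hazards: Mapping[str, float] = field(
        default_factory=lambda: {"renal": 0.015, "cv": 0.020, "death": 0.008}
    )
    study_end: str = "2019-06-30"

    # Structural coefficients, all confounding channels scaled by
    # ``confounding_strength``:
    #   anemia ~ lag anemia, lag eGFR deficit, lag treatment
    #   treatment ~ lag anemia
    #   hazard ~ current anemia (true_log_hr) + latent susceptibility U
    #   eGFR   ~ drift + anemia acceleration + U
    coef_anemia_prev: float = 1.8
    coef_anemia_egfr: float = 1.2      # per 5 mL/min/1.73 m2 below 58
    coef_anemia_treat: float = -1.0
    coef_treat_anemia: float = 2.2
    treat_intercept: float = -3.5
    coef_hazard_u: float = 0.6
    coef_egfr_u: float = -0.9
    egfr_noise_sd: float = 2.0

    # Small fractions of ineligible enrollment patterns, so cohort
    # construction has real exclusions to count.
    frac_never_low: float = 0.04
    frac_first_low: float = 0.02
    frac_prior_dialysis: float = 0.001

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3 (3-year renal endpoint)")
        for name in ("baseline_anemia_prob", "censoring_rate", "missingness_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.confounding_strength < 0:
            raise ValueError("confounding_strength must be >= 0")
        for o in OUTCOMES:
            if o not in self.true_log_hr or o not in self.base_hazards:
                raise ValueError(f"missing rates for outcome {o!r}")


def _scr_from_egfr(egfr, age, female):
    """Invert the three-variable Japanese eGFR equation for serum creatinine."""
    denom = 194.0 * np.power(age, -0.287) * np.where(female, 0.739, 1.0)
    return np.power(egfr / denom, -1.0 / 1.094)


def simulate_cohort(config: SimulationConfig):
    """Generate (checkups, claims, enrollment, truth) tables.

    Returns four DataFrames.  The first three conform to the raw input
    schemas of the cohort module; ``truth`` carries the hidden per-subject
    event/censoring days (measured from the index checkup), latent
    susceptibility, and the true exposure/treatment sequences, for test
    assertions only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    c = config.confounding_strength
    crit = AnemiaCriteria.default()
    study_end = np.datetime64(config.study_end)

    sid = np.arange(1, n + 1)
    female = rng.random(n) < 0.273
    age_index = np.clip(np.round(rng.normal(52.0, 8.0, n)), 21, 73)
    u = rng.standard_normal(n)
    smoker = (rng.random(n) < 0.205).astype(int)
    bmi0 = rng.normal(23.9, 3.7, n)
    dm_flag = rng.random(n) < 0.10
    dm_complicated = dm_flag & (rng.random(n) < 0.2)
    hba1c0 = rng.normal(5.5, 0.45, n) + 1.0 * dm_flag

    pattern = rng.random(n)
    never_low = pattern < config.frac_never_low
    first_low = (pattern >= config.frac_never_low) & (
        pattern < config.frac_never_low + config.frac_first_low
    )
    prior_dialysis = rng.random(n) < config.frac_prior_dialysis

    # Calendar scaffolding: enrollment starts 2006-2008, first checkup about
    # 13 months later (guaranteeing the 1-year lookback), annual cadence.
    start = np.datetime64("2006-01-01") + rng.integers(0, 1096, n).astype(
        "timedelta64[D]"
    )
    n_ck = config.n_years + 1  # checkup 0 = pre-index, checkup 1 = index
    ck_offsets = np.empty((n, n_ck), dtype=np.int64)
    ck_offsets[:, 0] = 380 + rng.integers(0, 21, n)
    gaps = 365 + rng.integers(-10, 11, (n, n_ck - 1))
    ck_offsets[:, 1:] = ck_offsets[:, [0]] + np.cumsum(gaps, axis=1)
    ck_dates = start[:, None] + ck_offsets.astype("timedelta64[D]")

    egfr_pre = np.clip(rng.normal(66.0, 5.0, n), 60.5, 110.0)
    egfr_index = np.clip(rng.normal(58.0, 1.5, n), 45.0, 59.5)
    egfr_pre[never_low] = np.clip(rng.normal(70.0, 5.0, never_low.sum()), 60.5, 110.0)
    egfr_index[never_low] = np.clip(
        rng.normal(68.0, 4.0, never_low.sum()), 60.5, 110.0
    )
    egfr_pre[first_low] = np.clip(rng.normal(55.0, 3.0, first_low.sum()), 40.0, 59.5)
    egfr_lo = np.where(never_low, 60.5, 8.0)

    drift, accel = config.egfr_drift
    K = config.n_years - 1  # post-index periods 0..K, checkup k at column k+1

    # Period-level state, simulated sequentially.
    egfr = np.empty((n, K + 1))
    anemia = np.zeros((n, K + 1), dtype=int)
    treat = np.zeros((n, K + 1), dtype=int)
    egfr[:, 0] = egfr_index
    a0 = _logit(config.baseline_anemia_prob)
    p = _expit(a0 + c * config.coef_anemia_egfr * (58.0 - egfr[:, 0]) / 5.0)
    anemia[:, 0] = rng.random(n) < p
    treat[:, 0] = rng.random(n) < _expit(
        config.treat_intercept + c * config.coef_treat_anemia * anemia[:, 0]
    )
    for k in range(1, K + 1):
        egfr[:, k] = np.clip(
            egfr[:, k - 1]
            + drift
            + accel * anemia[:, k - 1]
            + c * config.coef_egfr_u * u
            + rng.normal(0.0, config.egfr_noise_sd, n),
            egfr_lo,
            130.0,
        )
        pa = _expit(
            a0
            + config.coef_anemia_prev * anemia[:, k - 1]
            + c * config.coef_anemia_egfr * (58.0 - egfr[:, k - 1]) / 5.0
            + c * config.coef_anemia_treat * treat[:, k - 1]
        )
        anemia[:, k] = rng.random(n) < pa
        treat[:, k] = rng.random(n) < _expit(
            config.treat_intercept + c * config.coef_treat_anemia * anemia[:, k - 1]
        )

    # Hemoglobin consistent with the anemia classifier at each checkup's age.
    age_at = age_index[:, None] + (ck_offsets[:, 1:] - ck_offsets[:, [1]]) / DAYS_PER_YEAR
    cutoff = crit.cutoff_array(age_at, np.broadcast_to(female[:, None], age_at.shape))
    hb = np.where(
        anemia == 1,
        np.clip(cutoff - 0.3 - np.abs(rng.normal(0.8, 0.5, (n, K + 1))), 6.0, None),
        np.clip(cutoff + 0.3 + np.abs(rng.normal(1.8, 1.0, (n, K + 1))), None, 19.0),
    )

    # Event and censoring days measured from the index checkup.
    lam_c = -np.log(max(1.0 - config.censoring_rate, 1e-12))
    censor_day = (
        rng.exponential(1.0 / lam_c, n) * DAYS_PER_YEAR
        if lam_c > 0
        else np.full(n, np.inf)
    )
    period_start = (ck_offsets[:, 1:] - ck_offsets[:, [1]]).astype(float)
    period_len = np.empty_like(period_start)
    period_len[:, :-1] = np.diff(period_start, axis=1)
    period_len[:, -1] = 365.0

    event_day = {o: np.full(n, np.inf) for o in OUTCOMES}
    for o in OUTCOMES:
        base = config.base_hazards[o]
        beta = config.true_log_hr[o]
        alive = np.ones(n, dtype=bool)
        for k in range(K + 1):
            rate = base * np.exp(beta * anemia[:, k] + c * config.coef_hazard_u * u)
            t = rng.exponential(1.0, n) / rate * DAYS_PER_YEAR
            fire = alive & (t < period_len[:, k]) & ~np.isfinite(event_day[o])
            day = period_start[:, k] + t
            event_day[o][fire] = day[fire]
            if o == "death":
                alive &= ~fire
            else:
                alive &= ~fire  # only first occurrence per outcome matters

    # Death truncates everything; censoring truncates events after it.
    death_day = event_day["death"]
    for o in ("renal", "cv"):
        event_day[o][event_day[o] > death_day] = np.inf
        event_day[o][event_day[o] > censor_day] = np.inf

    index_date = ck_dates[:, 1]
    admin_end = ck_dates[:, -1] + np.timedelta64(365, "D")
    end_candidates = np.minimum(
        admin_end, np.broadcast_to(study_end, admin_end.shape)
    )
    censor_date = index_date + np.round(censor_day).astype("timedelta64[D]")
    death_date = np.where(
        np.isfinite(death_day),
        index_date + np.round(np.where(np.isfinite(death_day), death_day, 0)).astype(
            "timedelta64[D]"
        ),
        np.datetime64("NaT"),
    )
    end_date = np.minimum(end_candidates, censor_date)
    died = np.isfinite(death_day) & (death_date <= end_date)
    end_date = np.where(died, death_date, end_date)
    death_date = np.where(died, death_date, np.datetime64("NaT"))

    # ---- checkup table (long format); checkups after end_date are not observed
    rows = []
    pre_cut = crit.cutoff_array(age_index - 1.0, female)
    pre_hb = np.clip(pre_cut + 0.3 + np.abs(rng.normal(1.8, 1.0, n)), None, 19.0)
    prot_levels = np.array(["-", "+-", "1+", "2+", "3+"])
    prot_p = np.array([0.85, 0.09, 0.04, 0.015, 0.005])

    def prot_draw(size):
        return prot_levels[rng.choice(5, size=size, p=prot_p)]

    all_dates = np.concatenate([ck_dates[:, [0]], ck_dates[:, 1:]], axis=1)
    all_egfr = np.concatenate([egfr_pre[:, None], egfr], axis=1)
    all_hb = np.concatenate([pre_hb[:, None], hb], axis=1)
    for j in range(n_ck):
        d = all_dates[:, j]
        obs = d <= end_date if j > 0 else np.ones(n, dtype=bool)
        m = int(obs.sum())
        if m == 0:
            continue
        age_j = age_index[obs] + (
            (d[obs] - index_date[obs]) / np.timedelta64(1, "D")
        ) / DAYS_PER_YEAR
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": sid[obs],
                    "date": d[obs],
                    "scr": np.round(
                        _scr_from_egfr(all_egfr[obs, j], age_j, female[obs]), 3
                    ),
                    "hb": np.round(all_hb[obs, j], 1),
                    "hct": np.round(all_hb[obs, j] * 3.0 + rng.normal(0, 1.0, m), 1),
                    "bmi": np.round(bmi0[obs] + rng.normal(0, 0.5, m), 1),
                    "hba1c": np.round(hba1c0[obs] + rng.normal(0, 0.15, m), 1),
                    "sbp": np.round(rng.normal(125.0, 15.0, m), 0),
                    "proteinuria_dipstick": prot_draw(m),
                    "smoker": smoker[obs],
                }
            )
        )
    checkups = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["subject_id", "date"], kind="stable")
        .reset_index(drop=True)
    )

    # ---- claims table
    claim_parts = []

    def add_claims(mask_or_idx, dates, icd10, record_type, treatment_code):
        idx = np.flatnonzero(mask_or_idx) if mask_or_idx.dtype == bool else mask_or_idx
        if len(idx) == 0:
            return
        claim_parts.append(
            pd.DataFrame(
                {
                    "subject_id": sid[idx],
                    "date": dates,
                    "icd10": icd10,
                    "record_type": record_type,
                    "treatment_code": treatment_code,
                }
            )
        )

    # anemia-treatment pharmacy claims shortly after each treated checkup
    for k in range(K + 1):
        tmask = (treat[:, k] == 1) & (ck_dates[:, k + 1] <= end_date)
        idx = np.flatnonzero(tmask)
        if len(idx) == 0:
            continue
        kinds = rng.choice(
            ["oral_iron", "esa", "iv_iron"], size=len(idx), p=[0.9, 0.05, 0.05]
        )
        add_claims(
            idx,
            ck_dates[idx, k + 1] + np.timedelta64(15, "D"),
            "D638",
            "pharmacy",
            kinds,
        )

    # renal events -> dialysis (95%) or transplant claims
    ren = np.flatnonzero(np.isfinite(event_day["renal"]))
    if len(ren):
        is_tx = rng.random(len(ren)) < 0.05
        dts = index_date[ren] + np.round(event_day["renal"][ren]).astype(
            "timedelta64[D]"
        )
        add_claims(
            ren,
            dts,
            np.where(is_tx, TRANSPLANT_CODE, DIALYSIS_CODE),
            "inpatient",
            np.where(is_tx, "kidney_transplant", "chronic_dialysis"),
        )
    # CV events -> diagnosis claims
    cvi = np.flatnonzero(np.isfinite(event_day["cv"]))
    if len(cvi):
        codes = rng.choice(list(CV_EVENT_CODES), size=len(cvi))
        dts = index_date[cvi] + np.round(event_day["cv"][cvi]).astype("timedelta64[D]")
        add_claims(cvi, dts, codes, "inpatient", "")

    # background comorbidity claims in the lookback window (CCI fodder)
    look_len = (index_date - start) / np.timedelta64(1, "D")
    for code, pmask in [
        ("E119", dm_flag & ~dm_complicated),
        ("E112", dm_complicated),
        ("J449", rng.random(n) < 0.05),
        ("K760", rng.random(n) < 0.03),
        ("C349", rng.random(n) < 0.01),
        ("I219", rng.random(n) < 0.03),
        ("I509", rng.random(n) < 0.02),
    ]:
        idx = np.flatnonzero(pmask)
        if len(idx) == 0:
            continue
        offs = (rng.random(len(idx)) * look_len[idx]).astype("timedelta64[D]")
        add_claims(idx, start[idx] + offs, code, "outpatient", "")
    # antidiabetic prescriptions within 3 months pre-index for half of diabetics
    adm = np.flatnonzero(dm_flag & (rng.random(n) < 0.5))
    if len(adm):
        add_claims(
            adm,
            index_date[adm] - rng.integers(1, 90, len(adm)).astype("timedelta64[D]"),
            "E119",
            "pharmacy",
            "other_antidiabetic",
        )
    pdx = np.flatnonzero(prior_dialysis)
    if len(pdx):
        add_claims(
            pdx,
            index_date[pdx] - np.timedelta64(30, "D"),
            DIALYSIS_CODE,
            "inpatient",
            "chronic_dialysis",
        )

    claims = (
        pd.concat(claim_parts, ignore_index=True)
        .sort_values(["subject_id", "date", "icd10"], kind="stable")
        .reset_index(drop=True)
    )

    enrollment = pd.DataFrame(
        {
            "subject_id": sid,
            "sex": np.where(female, "F", "M"),
            "birth_year": (index_date.astype("datetime64[Y]").astype(int) + 1970)
            - age_index.astype(int),
            "start_date": start,
            "end_date": end_date,
            "death": died.astype(int),
            "death_date": death_date,
        }
    )

    fu_days = (end_date - index_date) / np.timedelta64(1, "D")
    truth = pd.DataFrame(
        {
            "subject_id": sid,
            "u": u,
            "index_date": index_date,
            "followup_days": fu_days,
            "censor_day": np.where(np.isfinite(censor_day), censor_day, np.nan),
            "renal_day": np.where(
                np.isfinite(event_day["renal"]), event_day["renal"], np.nan
            ),
            "cv_day": np.where(np.isfinite(event_day["cv"]), event_day["cv"], np.nan),
            "death_day": np.where(np.isfinite(death_day), death_day, np.nan),
            "exposures": ["".join(map(str, row)) for row in anemia],
            "treatments": ["".join(map(str, row)) for row in treat],
        }
    )

    if config.missingness_rate > 0:
        protect = checkups.groupby("subject_id").cumcount() <= 1
        checkups = inject_missingness(
            checkups,
            config.missingness_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
            protect=protect.to_numpy(),
        )

    return checkups, claims, enrollment, truth


MISSABLE_FIELDS = ("hb", "hba1c", "bmi", "smoker", "sbp")


def inject_missingness(checkups, rate, seed=0, protect=None):
    """Set a fraction of non-key checkup fields to missing, completely at random.

    ``protect`` is an optional boolean mask of rows whose ``hb`` must never be
    removed (index/pre-index rows, which eligibility requires).  Serum
    creatinine and dipstick proteinuria are never touched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    out = checkups.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    nrow = len(out)
    for col in MISSABLE_FIELDS:
        if col not in out.columns:
            continue
        mask = rng.random(nrow) < rate
        if col == "hb" and protect is not None:
            mask &= ~np.asarray(protect, dtype=bool)
        out[col] = out[col].astype(float).mask(mask)
    return out


def write_tables(outdir, checkups, claims, enrollment, truth=None):
    """Write the generated tables as UTF-8 CSV with ISO-8601 dates."""
    import os

    os.makedirs(outdir, exist_ok=True)
    checkups.to_csv(os.path.join(outdir, "checkups.csv"), index=False)
    claims.to_csv(os.path.join(outdir, "claims.csv"), index=False)
    enrollment.to_csv(os.path.join(outdir, "enrollment.csv"), index=False)
    if truth is not None:
        truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)
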