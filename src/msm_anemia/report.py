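"""Pipeline orchestration and publication-style reporting tables.

`run_pipeline` drives simulate/ingest -> cohort -> outcomes -> imputation ->
weights -> fits -> tables, logging subject counts at every filter step and
stamping every artifact with the seed and a config hash.  Reports are CSV
plus a plain-text summary: baseline characteristics with standardized mean
differences before/after weighting, incidence per 1000 patient-years,
hazard-ratio fits (baseline risk model, MSM, sensitivity battery), and
survival at years 1, 3, 6.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import codes as codes_mod
from .cohort import build_cohort
from .coxph import fit_weighted_cox
from .outcomes import AnemiaCriteria, derive_outcomes, egfr_slopes, DAYS_PER_YEAR
from .panel import attach_outcome, build_person_periods
from .simulate import SimulationConfig, simulate_cohort, write_tables
from .survival import breslow_curves, incidence_rate, km_estimator, person_time
from .weights import (
    WeightModelSpec,
    fit_baseline_ipw,
    fit_time_varying_ipw,
    simple_impute,
    truncate_weights,
)

log = logging.getLogger("msm_anemia")

BASELINE_MODEL_COVARIATES = [
    "age_at_index", "female", "index_egfr", "proteinuria_num", "cci_score",
    "hba1c", "sbp", "smoker",
]
DEFAULT_TV_DENOMINATOR = ["egfr", "egfr_lag", "anemia_treatment", "treatment_lag"]
DEFAULT_BASELINE_DENOMINATOR = ["egfr", "age", "female"]


@dataclass
class RunConfig:
    outdir: str = "msm_out"
    seed: int = 0
    # either paths to the three raw tables ...
    checkups_path: Optional[str] = None
    claims_path: Optional[str] = None
    enrollment_path: Optional[str] = None
    # ... or a simulation configuration
    simulate: Optional[SimulationConfig] = SimulationConfig()
    study_end: str = "2019-06-30"
    anemia_criteria: AnemiaCriteria = field(default_factory=AnemiaCriteria.default)
    code_map: Optional[Dict] = None
    weight_spec: WeightModelSpec = field(default_factory=lambda: WeightModelSpec(
        denominator=list(DEFAULT_TV_DENOMINATOR),
        baseline_denominator=list(DEFAULT_BASELINE_DENOMINATOR),
    ))
    outcomes: List[str] = field(default_factory=lambda: ["renal", "cv", "death"])
    run_msm: bool = True
    run_baseline: bool = True
    run_truncation: bool = True
    truncation_pcts: tuple = (1.0, 99.0)
    bootstrap_reps: int = 0
    survival_years: tuple = (1, 3, 6)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # analysis identity, not output location
        blob = json.dumps(d, default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def prevalence_percent(count: int, total: int, decimals: int = 1) -> float:
    """Table-style prevalence: 100 * count / total, rounded for reporting."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must be between 0 and total")
    return round(100.0 * count / total, decimals)


def standardized_mean_difference(df, covariates, group_col,
                                 weights: Optional[pd.Series] = None) -> pd.Series:
    """|m1 - m0| / sqrt((v1 + v0) / 2), weighted moments when weights given.

    Binary covariates use the proportion analogue (variance p(1-p)).
    """
    g = df[group_col].astype(bool).to_numpy()
    w = (np.asarray(weights, dtype=float) if weights is not None
         else np.ones(len(df)))
    out = {}
    for c in covariates:
        x = df[c].astype(float).to_numpy()
        res = []
        for mask in (g, ~g):
            ww, xx = w[mask], x[mask]
            ok = ~np.isnan(xx)
            ww, xx = ww[ok], xx[ok]
            m = np.average(xx, weights=ww)
            if set(np.unique(x[~np.isnan(x)])) <= {0.0, 1.0}:
                v = m * (1 - m)
            else:
                v = np.average((xx - m) ** 2, weights=ww)
            res.append((m, v))
        (m1, v1), (m0, v0) = res
        pooled = (v1 + v0) / 2.0
        if pooled == 0:
            if m1 != m0:
                raise ValueError(f"zero pooled variance with unequal means: {c}")
            out[c] = 0.0
        else:
            out[c] = abs(m1 - m0) / np.sqrt(pooled)
    return pd.Series(out, name="smd")


def _fit_summary(fit, label):
    ci = fit.confidence_intervals()
    ci.insert(0, "model", label)
    ci["n_subjects"] = fit.n_subjects
    ci["n_events"] = fit.n_events
    return ci.reset_index(names="covariate")


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the full analysis; returns the report bundle as a dict of tables."""
    os.makedirs(config.outdir, exist_ok=True)
    provenance = {"seed": config.seed, "config_hash": config.config_hash()}
    bundle: Dict[str, object] = {"provenance": provenance}

    stage = "ingest"
    try:
        if config.checkups_path:
            checkups = pd.read_csv(config.checkups_path, parse_dates=["date"])
            claims = pd.read_csv(config.claims_path, parse_dates=["date"])
            enrollment = pd.read_csv(
                config.enrollment_path,
                parse_dates=["start_date", "end_date", "death_date"],
            )
        else:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            checkups, claims, enrollment, _truth = simulate_cohort(sim)
        n_subjects_in = checkups["subject_id"].nunique()
        log.info("ingest: %d subjects", n_subjects_in)

        stage = "cohort"
        cohort, tally = build_cohort(
            checkups, claims, enrollment, study_end=config.study_end,
            criteria=config.anemia_criteria, code_map=config.code_map,
        )
        bundle["exclusion_tally"] = tally
        log.info("cohort: retained %d of %d", len(cohort), n_subjects_in)
        cohort["female"] = (cohort["sex"].astype(str).str.upper() == "F").astype(int)
        cohort["proteinuria_num"] = cohort["proteinuria"].astype(int)
        cohort["baseline_anemia"] = cohort["baseline_anemia"].astype(int)

        stage = "outcomes"
        cv_map = codes_mod.CV_EVENT_CODE_MAP
        checkups = checkups.copy()
        outcome_table = derive_outcomes(
            cohort, _with_egfr(checkups, enrollment), claims, cv_map
        )
        bundle["outcomes"] = outcome_table

        stage = "imputation"
        cohort, imp_log = simple_impute(
            cohort, baseline_cols=["bmi", "hba1c", "sbp", "smoker", "baseline_hb"],
        )
        bundle["imputation_log"] = imp_log

        stage = "baseline_weights"
        bspec = WeightModelSpec(
            baseline_denominator=[c for c in BASELINE_MODEL_COVARIATES
                                  if c in cohort.columns],
        )
        sw0, _diag0 = fit_baseline_ipw(cohort, bspec)
        cohort["sw_baseline"] = sw0.to_numpy()

        smd_cols = [c for c in BASELINE_MODEL_COVARIATES if c in cohort.columns]
        smd = pd.DataFrame({
            "unweighted": standardized_mean_difference(
                cohort, smd_cols, "baseline_anemia"),
            "weighted": standardized_mean_difference(
                cohort, smd_cols, "baseline_anemia", weights=cohort["sw_baseline"]),
        })
        bundle["baseline_smd"] = smd

        stage = "incidence"
        inc_rows = []
        for oc in config.outcomes:
            ot = outcome_table[outcome_table["outcome"] == oc].merge(
                cohort[["subject_id", "baseline_anemia"]], on="subject_id")
            for label, sub in [("total", ot),
                               ("anemia", ot[ot["baseline_anemia"] == 1]),
                               ("non-anemia", ot[ot["baseline_anemia"] == 0])]:
                py = person_time(sub)
                r = incidence_rate(int(sub["event"].sum()), py, n=len(sub))
                inc_rows.append({
                    "outcome": oc, "group": label, "n": len(sub),
                    "person_years": round(py, 1), "events": r.events,
                    "rate_per_1000py": r.rate, "ci_lower": r.ci_lower,
                    "ci_upper": r.ci_upper,
                })
        bundle["incidence"] = pd.DataFrame(inc_rows)

        stage = "person_periods"
        pp = build_person_periods(cohort, _with_egfr(checkups, enrollment), claims,
                                  criteria=config.anemia_criteria)
        pp, pp_log = simple_impute(
            pp, timevarying_cols=["hb", "anemia", "egfr", "hba1c", "smoker"],
            subject_col="subject_id", order_col="k",
        )
        pp["anemia"] = (pp["anemia"] >= 0.5).astype(float)
        g = pp.groupby("subject_id", sort=False)
        pp["anemia_lag"] = g["anemia"].shift(1).fillna(0.0)
        pp["egfr_lag"] = g["egfr"].shift(1)
        pp["egfr_lag"] = pp["egfr_lag"].fillna(pp["egfr"])

        stage = "time_varying_weights"
        pp, wdiag = fit_time_varying_ipw(pp, config.weight_spec)
        bundle["weight_diagnostics"] = {
            "mean_weight_by_period": wdiag["mean_weight_by_period"],
        }

        stage = "fits"
        fits = []
        curves_rows = []
        surv_rows = []
        for oc in config.outcomes:
            rows = attach_outcome(pp, outcome_table, oc)
            if config.run_msm:
                fit = fit_weighted_cox(rows, covariates=["anemia"], weight_col="sw")
                fits.append(_fit_summary(fit, f"msm_{oc}"))
                always, never = breslow_curves(fit, "anemia")
                for curve in (always, never):
                    for yr in config.survival_years:
                        surv_rows.append({
                            "outcome": oc, "model": "breslow_msm",
                            "group": curve.regime, "year": yr,
                            "survival": curve.at(yr * 365.25),
                        })
                    curves_rows.append(pd.DataFrame({
                        "outcome": oc, "regime": curve.regime,
                        "time_days": curve.times, "survival": curve.survival,
                        "ci_lower": curve.ci_lower, "ci_upper": curve.ci_upper,
                    }))
                if config.run_truncation:
                    rows_t = rows.copy()
                    rows_t["sw"] = truncate_weights(
                        rows_t["sw"], *config.truncation_pcts)
                    fit_t = fit_weighted_cox(rows_t, covariates=["anemia"],
                                             weight_col="sw")
                    fits.append(_fit_summary(fit_t, f"msm_{oc}_truncated"))
            if config.run_baseline:
                ot = outcome_table[outcome_table["outcome"] == oc].merge(
                    cohort, on="subject_id")
                ot["stop_day"] = ot["time_days"].astype(float)
                ot = ot[ot["stop_day"] > 0]
                ot["start_day"] = 0.0
                covs = ["baseline_anemia"] + [c for c in BASELINE_MODEL_COVARIATES
                                              if c in ot.columns]
                if oc == "cv" and "cv_history" in ot.columns:
                    ot["cv_history"] = ot["cv_history"].astype(int)
                    covs.append("cv_history")
                fitb = fit_weighted_cox(ot, covariates=covs)
                fits.append(_fit_summary(fitb, f"baseline_{oc}"))
                # descriptive KM at the reporting years
                for label, sub, wcol in [
                    ("unweighted_km", ot, None),
                    ("weighted_km", ot, "sw_baseline"),
                ]:
                    for grp, gsub in sub.groupby("baseline_anemia"):
                        km = km_estimator(
                            gsub["stop_day"] / DAYS_PER_YEAR, gsub["event"],
                            weights=gsub[wcol] if wcol else None,
                            times=list(config.survival_years),
                        )
                        for _, row in km.iterrows():
                            surv_rows.append({
                                "outcome": oc, "model": label,
                                "group": "anemia" if grp else "non-anemia",
                                "year": row["time"], "survival": row["survival"],
                                "ci_lower": row["ci_lower"],
                                "ci_upper": row["ci_upper"],
                            })

        bundle["fits"] = pd.concat(fits, ignore_index=True)
        bundle["survival_at_years"] = pd.DataFrame(surv_rows)
        bundle["regime_curves"] = (pd.concat(curves_rows, ignore_index=True)
                                   if curves_rows else pd.DataFrame())

        stage = "slopes"
        slopes = egfr_slopes(_with_egfr(checkups, enrollment), cohort)
        sl = cohort[["subject_id", "baseline_anemia"]].merge(
            slopes.reset_index(), on="subject_id")
        bundle["egfr_slope_by_anemia"] = sl.groupby("baseline_anemia")[
            "egfr_slope"].agg(["mean", "std", "count"])
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _write_bundle(config, bundle)
    return bundle


def _with_egfr(checkups, enrollment):
    """Attach the Japanese-equation eGFR to every checkup row."""
    if "egfr" in checkups.columns:
        return checkups
    enr = enrollment.set_index("subject_id")
    ck = checkups.copy()
    ck["date"] = pd.to_datetime(ck["date"])
    sex = ck["subject_id"].map(enr["sex"]).astype(str).str.upper()
    by = ck["subject_id"].map(enr["birth_year"])
    age = (ck["date"] - pd.to_datetime(by.astype(int).astype(str) + "-01-01")
           ).dt.days / DAYS_PER_YEAR
    ck["egfr"] = np.where(
        ck["scr"].notna() & (ck["scr"] > 0),
        194.0 * ck["scr"] ** -1.094 * np.maximum(age, 18.0) ** -0.287
        * np.where(sex == "F", 0.739, 1.0),
        np.nan,
    )
    return ck


def _write_bundle(config: RunConfig, bundle: Dict) -> None:
    out = config.outdir
    prov = dict(bundle["provenance"])
    with open(os.path.join(out, "provenance.json"), "w") as fh:
        json.dump(prov, fh, indent=1, sort_keys=True)
    with open(os.path.join(out, "exclusion_tally.json"), "w") as fh:
        json.dump(bundle["exclusion_tally"], fh, indent=1, sort_keys=True)
    for key in ("outcomes", "incidence", "fits", "survival_at_years",
                "regime_curves", "baseline_smd", "imputation_log"):
        obj = bundle.get(key)
        if isinstance(obj, pd.DataFrame) and len(obj):
            obj.to_csv(os.path.join(out, f"{key}.csv"),
                       index=key in ("baseline_smd",))
    sl = bundle.get("egfr_slope_by_anemia")
    if sl is not None:
        sl.to_csv(os.path.join(out, "egfr_slope_by_anemia.csv"))
    lines = ["msm-anemia report", f"seed={prov['seed']}",
             f"config={prov['config_hash']}", ""]
    lines.append("Exclusion tally:")
    for k, v in bundle["exclusion_tally"].items():
        lines.append(f"  {k}: {v}")
    if isinstance(bundle.get("fits"), pd.DataFrame):
        lines.append("")
        lines.append("Hazard ratios:")
        for _, r in bundle["fits"].iterrows():
            if r["covariate"] in ("anemia", "baseline_anemia"):
                lines.append(
                    f"  {r['model']}: HR {r['hr']:.3f} "
                    f"[{r['hr_lower']:.3f}-{r['hr_upper']:.3f}] "
                    f"(n={r['n_subjects']}, events={r['n_events']})"
                )
    with open(os.path.join(out, "summary.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
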