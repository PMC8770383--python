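"""Counterfactual survival curves, Kaplan-Meier, Fine-Gray, PS matching, rates.

The marginal structural Cox fit yields a weighted Breslow cumulative
baseline hazard; exponentiating under the two static regimes gives the
"always-exposed" and "never-exposed" survival curves.  Confidence bands come
from a subject-level nonparametric bootstrap (weights and Cox refitted per
replicate).  Incidence rates use exact Poisson (chi-square inversion)
intervals per 1000 patient-years.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coxph import SurvivalFit, fit_weighted_cox

DAYS_PER_YEAR = 365.25


@dataclass
class RegimeCurve:
    """Counterfactual survival curve S(t | static exposure regime)."""

    regime: str  # "always-exposed" or "never-exposed"
    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


@dataclass
class IncidenceResult:
    n: int
    person_years: float
    events: int
    rate: float       # per 1000 patient-years
    ci_lower: float
    ci_upper: float


def _regime_survival(fit: SurvivalFit, exposure: str, times) -> dict:
    cum = fit.baseline_cumhaz
    lam = np.interp(times, cum["time"], cum["cumhaz"], left=0.0)
    hr = float(np.exp(fit.params[exposure]))
    return {
        "always-exposed": np.exp(-lam * hr),
        "never-exposed": np.exp(-lam),
    }


def breslow_curves(fit: SurvivalFit, exposure: Optional[str] = None,
                   times: Optional[Sequence[float]] = None,
                   refit: Optional[Callable[[np.random.Generator], SurvivalFit]] = None,
                   n_boot: int = 0, seed: int = 0, alpha: float = 0.05):
    """(always-exposed, never-exposed) curves from the weighted Breslow estimator.

    ``refit``, if given, is called with a bootstrap Generator and must return
    a refitted SurvivalFit on a subject-level resample (recomputing weights);
    percentile bands over ``n_boot`` replicates.  Without it the band
    collapses onto the point estimate.
    """
    exposure = exposure or fit.covariates[0]
    if times is None:
        tmax = fit.baseline_cumhaz["time"].max()
        times = np.unique(np.concatenate([
            fit.baseline_cumhaz["time"].to_numpy(), [0.0, tmax]]))
    times = np.asarray(sorted(times), dtype=float)
    point = _regime_survival(fit, exposure, times)

    bands = {k: (v.copy(), v.copy()) for k, v in point.items()}
    if refit is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = {k: np.empty((n_boot, len(times))) for k in point}
        b = 0
        attempts = 0
        while b < n_boot and attempts < 5 * n_boot:
            attempts += 1
            try:
                bfit = refit(rng)
            except Exception:
                continue  # e.g. zero events in the resample: draw again
            sb = _regime_survival(bfit, exposure, times)
            for k in point:
                draws[k][b] = sb[k]
            b += 1
        if b < n_boot:
            raise RuntimeError("bootstrap failed to produce enough replicates")
        for k in point:
            lo = np.quantile(draws[k], alpha / 2, axis=0)
            hi = np.quantile(draws[k], 1 - alpha / 2, axis=0)
            bands[k] = (np.minimum(lo, point[k]), np.maximum(hi, point[k]))

    out = []
    for k in ("always-exposed", "never-exposed"):
        out.append(RegimeCurve(
            regime=k, times=times, survival=point[k],
            ci_lower=bands[k][0], ci_upper=bands[k][1],
        ))
    return tuple(out)


def km_estimator(durations, events, weights=None,
                 times: Optional[Sequence[float]] = None,
                 alpha: float = 0.05) -> pd.DataFrame:
    """(Weighted) product-limit estimator with Greenwood-type intervals."""
    import warnings

    from lifelines import KaplanMeierFitter
    from lifelines.exceptions import StatisticalWarning

    kmf = KaplanMeierFitter(alpha=alpha)
    with warnings.catch_warnings():
        # non-integer IPW weights are intentional here
        warnings.simplefilter("ignore", StatisticalWarning)
        kmf.fit(durations, event_observed=events, weights=weights)
    if times is None:
        times = kmf.survival_function_.index.to_numpy()
    times = np.asarray(times, dtype=float)
    s = kmf.survival_function_at_times(times).to_numpy()
    ci = kmf.confidence_interval_survival_function_
    # step-function semantics: use the last value at or before t
    lo_s = pd.Series(ci.iloc[:, 0].to_numpy(), index=ci.index).reindex(
        ci.index.union(times)).ffill().reindex(times).to_numpy()
    hi_s = pd.Series(ci.iloc[:, 1].to_numpy(), index=ci.index).reindex(
        ci.index.union(times)).ffill().reindex(times).to_numpy()
    lo, hi = np.nan_to_num(lo_s, nan=1.0), np.nan_to_num(hi_s, nan=1.0)
    return pd.DataFrame({"time": times, "survival": s,
                         "ci_lower": np.minimum(lo, hi),
                         "ci_upper": np.maximum(lo, hi)})


def _censoring_km(time, status):
    """Step function (times, G) of the censoring-survival distribution."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=(np.asarray(status) == 0).astype(int))
    sf = kmf.survival_function_
    return sf.index.to_numpy(), sf.iloc[:, 0].to_numpy()


def _g_left(gt, gv, t):
    """Left limit G(t-) of the censoring KM step function."""
    idx = np.searchsorted(gt, t, side="left") - 1
    return np.where(idx >= 0, gv[np.maximum(idx, 0)], 1.0)


def fit_fine_gray(df, time_col: str = "time_days", status_col: str = "status",
                  covariates=None, weight_col: Optional[str] = None,
                  cluster_col: str = "subject_id") -> SurvivalFit:
    """Sub-distribution hazard model (Fine & Gray) for the event of interest.

    ``status``: 0 censored, 1 event of interest, 2 competing event (death).
    Subjects failing from the competing event stay in the risk set after
    their death, down-weighted by the inverse probability of remaining
    uncensored, G(t-)/G(s-); the augmented data are fitted with the weighted
    Cox machinery.  With no competing events this reduces exactly to the
    cause-specific model (logged, allowed).
    """
    if covariates is None:
        raise ValueError("covariates must be named explicitly")
    time = df[time_col].to_numpy(dtype=float)
    status = df[status_col].to_numpy()
    w = (df[weight_col].to_numpy(dtype=float) if weight_col else np.ones(len(df)))
    ids = df[cluster_col].to_numpy()
    X = df[list(covariates)]

    event_times = np.unique(time[status == 1])
    rows = []

    base = pd.DataFrame({
        "subject_id": ids, "start_day": 0.0, "stop_day": time,
        "event": (status == 1).astype(int), "w": w,
    })
    for c in covariates:
        base[c] = X[c].to_numpy()
    rows.append(base)

    comp = status == 2
    if comp.any() and len(event_times):
        gt, gv = _censoring_km(time, status)
        tau = event_times.max()
        for i in np.flatnonzero(comp):
            s = time[i]
            later = event_times[event_times > s]
            if len(later) == 0:
                continue
            gs = float(_g_left(gt, gv, np.array([s]))[0])
            bounds = np.concatenate([[s], later])
            g_at = _g_left(gt, gv, later)
            seg = pd.DataFrame({
                "subject_id": ids[i],
                "start_day": bounds[:-1],
                "stop_day": bounds[1:],
                "event": 0,
                "w": w[i] * (g_at / gs if gs > 0 else 0.0),
            })
            for c in covariates:
                seg[c] = X[c].iloc[i]
            rows.append(seg)

    aug = pd.concat(rows, ignore_index=True)
    aug = aug[aug["w"] > 0]
    return fit_weighted_cox(
        aug, stop_col="stop_day", event_col="event", covariates=list(covariates),
        start_col="start_day", weight_col="w", cluster_col="subject_id",
    )


def ps_match(cohort, exposure_col: str, covariates=None, caliper: float = 0.25,
             caliper_scale: str = "sd",
             logit_ps: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Greedy 1:1 nearest-neighbor matching on the logit propensity score.

    Exposed subjects are processed in descending PS order (ties broken by
    subject id); the caliper is ``caliper`` x SD of the logit PS
    (``caliper_scale="raw"`` uses it as an absolute logit distance).
    Returns a DataFrame of matched pairs; unmatched exposed subjects are
    counted in ``.attrs['n_unmatched']``.
    """
    a = cohort[exposure_col].astype(float).to_numpy()
    if logit_ps is None:
        import statsmodels.api as sm

        X = np.column_stack([np.ones(len(cohort))]
                            + [cohort[c].to_numpy(float) for c in covariates])
        res = sm.Logit(a, X).fit(disp=0, method="newton", maxiter=100)
        logit_ps = X @ res.params
    else:
        logit_ps = np.asarray(logit_ps, dtype=float)
    width = caliper * (logit_ps.std(ddof=1) if caliper_scale == "sd" else 1.0)

    ids = cohort["subject_id"].to_numpy()
    exp_idx = np.flatnonzero(a >= 0.5)
    ctl_idx = np.flatnonzero(a < 0.5)
    if len(exp_idx) == 0 or len(ctl_idx) == 0:
        raise ValueError("no overlap: need both exposed and unexposed subjects")

    order = np.lexsort((ids[exp_idx], -logit_ps[exp_idx]))
    exp_sorted = exp_idx[order]
    ctl_sorted = ctl_idx[np.lexsort((ids[ctl_idx], logit_ps[ctl_idx]))]
    avail_ps = logit_ps[ctl_sorted].copy()
    avail_id = ctl_sorted.copy()

    pairs = []
    n_unmatched = 0
    for ei in exp_sorted:
        if len(avail_ps) == 0:
            n_unmatched += 1
            continue
        target = logit_ps[ei]
        j = np.searchsorted(avail_ps, target)
        best, bestd = -1, np.inf
        for cand in (j - 1, j):
            if 0 <= cand < len(avail_ps):
                d = abs(avail_ps[cand] - target)
                if d < bestd - 1e-15 or (abs(d - bestd) <= 1e-15 and best >= 0
                                         and ids[avail_id[cand]] < ids[avail_id[best]]):
                    best, bestd = cand, d
        if best >= 0 and bestd <= width:
            pairs.append((ids[ei], ids[avail_id[best]], logit_ps[ei],
                          avail_ps[best]))
            avail_ps = np.delete(avail_ps, best)
            avail_id = np.delete(avail_id, best)
        else:
            n_unmatched += 1

    out = pd.DataFrame(pairs, columns=["exposed_id", "control_id",
                                       "exposed_logit_ps", "control_logit_ps"])
    if len(out) == 0:
        raise ValueError("no overlap: zero matches within the caliper")
    out.attrs["n_unmatched"] = n_unmatched
    out.attrs["caliper_width"] = float(width)
    return out


def incidence_rate(events: int, person_years: float,
                   alpha: float = 0.05, n: Optional[int] = None) -> IncidenceResult:
    """Events per 1000 patient-years with an exact Poisson interval."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if events < 0:
        raise ValueError("events must be non-negative")
    scale = 1000.0 / person_years
    rate = events * scale
    lo = (stats.chi2.ppf(alpha / 2, 2 * events) / 2.0) * scale if events > 0 else 0.0
    hi = (stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2.0) * scale
    return IncidenceResult(
        n=int(n) if n is not None else events,
        person_years=float(person_years), events=int(events),
        rate=round(rate, 2), ci_lower=round(lo, 2), ci_upper=round(hi, 2),
    )


def person_time(outcome_table, group: Optional[pd.Series] = None):
    """Person-years from follow-up (event-or-censoring) times in days."""
    t = outcome_table["time_days"].to_numpy(dtype=float)
    if np.any(t < 0):
        raise ValueError("negative follow-up time")
    py = t / DAYS_PER_YEAR
    if group is None:
        return float(py.sum())
    return pd.Series(py, index=outcome_table.index).groupby(
        np.asarray(group)).sum()
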