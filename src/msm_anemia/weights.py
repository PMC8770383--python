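"""Stabilized inverse-probability-of-treatment weights.

Baseline (point-exposure) weights are the ratio of an intercept-only to a
full logistic model's predicted probability of the observed exposure.  The
time-varying weights are the period-by-period running product of
numerator/denominator predicted probabilities from pooled logistic models:
the numerator conditions on exposure history and a restricted-cubic-spline
function of time since index; the denominator additionally conditions on
covariate history.  At the index period both models use baseline covariates
alone.  A multinomial variant handles hemoglobin-quintile exposures.

Model fitting is Newton-Raphson via statsmodels; separation and
non-convergence raise with diagnostics instead of being silently
regularized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

MIN_PROB = 1e-12


class SeparationError(RuntimeError):
    pass


@dataclass
class WeightModelSpec:
    """Covariate lists by column name; denominator must contain the numerator."""

    denominator: List[str] = field(default_factory=list)
    numerator: List[str] = field(default_factory=list)
    baseline_denominator: List[str] = field(default_factory=list)
    baseline_numerator: List[str] = field(default_factory=list)
    n_knots: int = 5
    link: str = "logistic"
    truncation: Optional[Tuple[float, float]] = None
    history_count: bool = False  # add cumulative count of exposed periods

    def __post_init__(self):
        if not set(self.numerator) <= set(self.denominator):
            raise ValueError("denominator covariates must contain the numerator's")
        if self.n_knots < 3:
            raise ValueError("spline needs at least 3 knots")


def _fit_logit(y, X, label: str):
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if len(np.unique(y)) < 2:
        raise SeparationError(f"{label}: exposure is constant; cannot fit")
    model = sm.Logit(y, X)
    try:
        res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    except Exception as exc:  # PerfectSeparation and numerical failures
        raise SeparationError(f"{label}: logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError(f"{label}: Newton-Raphson did not converge")
    if np.abs(res.params).max() > 30:
        raise SeparationError(
            f"{label}: separation suspected (|coef| = {np.abs(res.params).max():.1f})"
        )
    return res


def _design(df, cols):
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in cols]
    )
    if np.isnan(X).any():
        bad = [c for c in cols if df[c].isna().any()]
        raise ValueError(f"missing values in design columns {bad}; impute first")
    return X


def _prob_observed(p1, a):
    p = np.where(a >= 0.5, p1, 1.0 - p1)
    if np.any(p <= 0):
        row = int(np.argmin(p))
        raise FloatingPointError(
            f"non-positive predicted probability at row {row}: p={p[row]}"
        )
    return np.clip(p, MIN_PROB, 1.0)


def fit_baseline_ipw(cohort, spec: WeightModelSpec,
                     exposure: str = "baseline_anemia"):
    """Per-subject stabilized weight P(A0=a) / P(A0=a | baseline covariates)."""
    a = cohort[exposure].astype(float).to_numpy()
    X_den = _design(cohort, spec.baseline_denominator)
    den = _fit_logit(a, X_den, "baseline denominator")
    if spec.baseline_numerator == spec.baseline_denominator:
        num = den
        X_num = X_den
    else:
        X_num = _design(cohort, spec.baseline_numerator)
        num = _fit_logit(a, X_num, "baseline numerator")
    p_den = _prob_observed(den.predict(X_den), a)
    p_num = _prob_observed(num.predict(X_num), a)
    sw = p_num / p_den
    return pd.Series(sw, index=cohort.index, name="sw"), {
        "denominator_params": den.params,
        "numerator_params": num.params,
        "mean_weight": float(sw.mean()),
    }


def fit_time_varying_ipw(pp, spec: WeightModelSpec, exposure: str = "anemia",
                         subject_col: str = "subject_id", period_col: str = "k",
                         time_col: str = "start_day"):
    """Stabilized weights sw_ik for a person-period table.

    Expects one row per subject x checkup period with the exposure, its lag
    (``<exposure>_lag``, 0 at k=0), and the covariate columns named by
    ``spec``.  Returns (table with ``sw``/``sw_period`` columns, diagnostics).
    """
    from .splines import rcs_basis, rcs_knots

    pp = pp.sort_values([subject_col, period_col], kind="stable").copy()
    a = pp[exposure].astype(float).to_numpy()
    lag_col = f"{exposure}_lag"
    k = pp[period_col].to_numpy()
    base = k == 0
    ratio = np.ones(len(pp))

    # index period: baseline covariates alone
    b0 = pp[base]
    sw0, diag0 = fit_baseline_ipw(b0, spec, exposure=exposure)
    ratio[base] = sw0.to_numpy()

    diag = {"baseline": diag0}
    later = ~base
    if later.any():
        sub = pp[later]
        knots = rcs_knots(sub[time_col].to_numpy(), spec.n_knots)
        basis = rcs_basis(sub[time_col].to_numpy(), knots)
        hist_cols = [sub[lag_col].to_numpy(dtype=float)]
        if spec.history_count:
            hist_cols.append(sub[f"{exposure}_cum"].to_numpy(dtype=float))
        hist = np.column_stack(hist_cols)
        ones = np.ones(len(sub))
        X_num = np.column_stack([ones, hist, basis])
        if spec.numerator:
            X_num = np.column_stack([X_num, sub[spec.numerator].to_numpy(float)])
        X_den = np.column_stack([ones, hist, basis,
                                 _design(sub, spec.denominator)[:, 1:]])
        y = a[later]
        den = _fit_logit(y, X_den, "pooled denominator")
        if spec.numerator == spec.denominator:
            num, X_num = den, X_den
        else:
            num = _fit_logit(y, X_num, "pooled numerator")
        p_den = _prob_observed(den.predict(X_den), y)
        p_num = _prob_observed(num.predict(X_num), y)
        ratio[later] = p_num / p_den
        diag["pooled"] = {
            "knots": knots,
            "denominator_params": den.params,
            "numerator_params": num.params,
        }

    pp["sw_period"] = ratio
    pp["sw"] = pp.groupby(subject_col, sort=False)["sw_period"].cumprod()
    diag["mean_weight_by_period"] = pp.groupby(period_col)["sw"].mean()
    return pp, diag


def truncate_weights(weights, lower_pct: float = 1.0, upper_pct: float = 99.0):
    """Winsorize weights at empirical percentiles (linear interpolation)."""
    if lower_pct >= upper_pct:
        raise ValueError("lower percentile must be below upper percentile")
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty weights")
    lo, hi = np.percentile(w, [lower_pct, upper_pct])
    out = np.clip(w, lo, hi)
    if isinstance(weights, pd.Series):
        return pd.Series(out, index=weights.index, name=weights.name)
    return out


def assign_hb_quintiles(cohort, hb_col: str = "baseline_hb", by: str = "sex",
                        n_cat: int = 5) -> pd.Series:
    """Quintile category (1 = lowest ... n_cat = highest) within sex."""
    def cut(s):
        return pd.qcut(s, n_cat, labels=False, duplicates="drop") + 1

    q = cohort.groupby(by, group_keys=False)[hb_col].apply(cut)
    return q.rename("hb_quintile").astype(int)


def _fit_mnlogit(y, X, label):
    cats = np.unique(y)
    if len(cats) < 2:
        raise SeparationError(f"{label}: exposure category is constant")
    recode = {cc: i for i, cc in enumerate(cats)}
    yy = np.asarray([recode[v] for v in y])
    try:
        res = sm.MNLogit(yy, X).fit(method="newton", maxiter=200, disp=0)
    except Exception as exc:
        raise SeparationError(f"{label}: multinomial fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError(f"{label}: multinomial fit did not converge")
    return res, recode


def _prob_observed_mn(res, X, y, recode):
    p = res.predict(X)  # n x n_cat, columns in recoded order
    idx = np.asarray([recode[v] for v in y])
    probs = np.asarray(p)[np.arange(len(y)), idx]
    if np.any(probs <= 0):
        raise FloatingPointError("non-positive multinomial probability")
    return np.clip(probs, MIN_PROB, 1.0)


def fit_quintile_weights(pp, spec: WeightModelSpec, exposure: str = "hb_quintile",
                         subject_col: str = "subject_id", period_col: str = "k",
                         time_col: str = "start_day"):
    """Stabilized weights for a categorical (Hb-quintile) exposure.

    Same product structure as the binary weights with multinomial
    numerator/denominator probabilities of the observed category; the lag
    enters as indicator columns.
    """
    from .splines import rcs_basis, rcs_knots

    pp = pp.sort_values([subject_col, period_col], kind="stable").copy()
    y = pp[exposure].to_numpy()
    lag_col = f"{exposure}_lag"
    base = pp[period_col].to_numpy() == 0
    ratio = np.ones(len(pp))

    b0 = pp[base]
    Xd0 = _design(b0, spec.baseline_denominator)
    den0, rec0 = _fit_mnlogit(b0[exposure].to_numpy(), Xd0, "baseline denominator")
    Xn0 = _design(b0, spec.baseline_numerator)
    num0, _ = _fit_mnlogit(b0[exposure].to_numpy(), Xn0, "baseline numerator")
    ratio[base] = (
        _prob_observed_mn(num0, Xn0, b0[exposure].to_numpy(), rec0)
        / _prob_observed_mn(den0, Xd0, b0[exposure].to_numpy(), rec0)
    )

    later = ~base
    if later.any():
        sub = pp[later]
        knots = rcs_knots(sub[time_col].to_numpy(), spec.n_knots)
        basis = rcs_basis(sub[time_col].to_numpy(), knots)
        lag_dum = pd.get_dummies(sub[lag_col], drop_first=True).to_numpy(float)
        ones = np.ones(len(sub))
        X_num = np.column_stack([ones, lag_dum, basis])
        X_den = X_num
        if spec.denominator:
            X_den = np.column_stack([X_den, sub[spec.denominator].to_numpy(float)])
        yy = sub[exposure].to_numpy()
        den, rec = _fit_mnlogit(yy, X_den, "pooled denominator")
        num, _ = _fit_mnlogit(yy, X_num, "pooled numerator")
        ratio[later] = (
            _prob_observed_mn(num, X_num, yy, rec)
            / _prob_observed_mn(den, X_den, yy, rec)
        )

    pp["sw_period"] = ratio
    pp["sw"] = pp.groupby(subject_col, sort=False)["sw_period"].cumprod()
    return pp


def simple_impute(df, baseline_cols=None, timevarying_cols=None,
                  subject_col: str = "subject_id", order_col: Optional[str] = None):
    """Simple imputation: cohort median (continuous) / mode (categorical) for
    baseline covariates; last observation carried forward, falling back to
    the cohort fill, for time-varying covariates.  Returns (table, log)."""
    out = df.copy()
    log = []
    baseline_cols = baseline_cols or []
    timevarying_cols = timevarying_cols or []

    def cohort_fill(col):
        s = out[col]
        if s.dropna().empty:
            raise ValueError(f"column {col!r} is fully missing; cannot impute")
        if pd.api.types.is_numeric_dtype(s) and s.dropna().nunique() > 2:
            return float(s.median())
        return s.mode().iloc[0]

    for col in timevarying_cols:
        if col not in out.columns:
            continue
        if order_col is not None:
            out = out.sort_values([subject_col, order_col], kind="stable")
        before = out[col].isna()
        out[col] = out.groupby(subject_col, sort=False)[col].ffill()
        locf = before & out[col].notna()
        for i in out.index[locf]:
            log.append({"row": i, "column": col, "method": "locf",
                        "value": out.at[i, col]})
        still = out[col].isna()
        if still.any():
            fill = cohort_fill(col)
            for i in out.index[still]:
                log.append({"row": i, "column": col, "method": "cohort",
                            "value": fill})
            out[col] = out[col].fillna(fill)

    for col in baseline_cols:
        if col not in out.columns:
            continue
        miss = out[col].isna()
        if not miss.any():
            continue
        fill = cohort_fill(col)
        for i in out.index[miss]:
            log.append({"row": i, "column": col, "method": "baseline", "value": fill})
        out[col] = out[col].fillna(fill)

    log_df = pd.DataFrame(log, columns=["row", "column", "method", "value"])
    return out, log_df
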