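"""Spline basis, imputation, stabilized weights: oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from msm_anemia import (
    WeightModelSpec,
    fit_baseline_ipw,
    fit_time_varying_ipw,
    fit_quintile_weights,
    rcs_basis,
    rcs_knots,
    simple_impute,
    truncate_weights,
)
from msm_anemia.weights import assign_hb_quintiles


class TestRcsBasis:
    KNOTS = np.array([10.0, 100.0, 300.0, 700.0, 1500.0])

    def test_nonlinear_terms_vanish_at_and_below_first_knot(self):
        b = rcs_basis([0.0, 5.0, 10.0], self.KNOTS)
        assert np.allclose(b[:, 1:], 0.0)

    def test_linear_in_right_tail(self):
        t = np.array([5000.0, 6000.0, 7000.0])
        b = rcs_basis(t, self.KNOTS)
        second_diff = b[2] - 2 * b[1] + b[0]
        assert np.allclose(second_diff, 0.0, atol=1e-6)

    def test_matches_published_macro_formula(self):
        """Independent scalar transcription of the RCSPLINE truncated-cube
        formula, evaluated on a grid."""
        k = self.KNOTS
        def macro(x):
            out = [x]
            tk = k[4]
            tk1 = k[3]
            for j in range(3):
                term = max(x - k[j], 0.0) ** 3
                term -= max(x - tk1, 0.0) ** 3 * (tk - k[j]) / (tk - tk1)
                term += max(x - tk, 0.0) ** 3 * (tk1 - k[j]) / (tk - tk1)
                out.append(term / (tk - k[0]) ** 2)
            return out

        grid = np.linspace(0, 2000, 20)
        mine = rcs_basis(grid, k)
        ref = np.array([macro(x) for x in grid])
        assert np.max(np.abs(mine - ref)) < 1e-10

    def test_validation(self):
        with pytest.raises(ValueError):
            rcs_basis([1.0], [1, 2])
        with pytest.raises(ValueError):
            rcs_basis([1.0], [3, 2, 1, 4, 5])

    def test_default_knot_quantiles(self):
        x = np.arange(1001.0)
        assert np.allclose(rcs_knots(x, 5),
                           np.quantile(x, [0.05, 0.275, 0.5, 0.725, 0.95]))


class TestSimpleImpute:
    def test_no_missing_is_identity_with_empty_log(self):
        df = pd.DataFrame({"subject_id": [1, 2], "hba1c": [5.0, 6.0]})
        out, log = simple_impute(df, baseline_cols=["hba1c"])
        pd.testing.assert_frame_equal(out, df)
        assert log.empty

    def test_median_fill_for_continuous_baseline(self):
        df = pd.DataFrame({"subject_id": [1, 2, 3, 4],
                           "hba1c": [5.0, 6.0, 7.0, np.nan]})
        out, log = simple_impute(df, baseline_cols=["hba1c"])
        assert out["hba1c"].iloc[3] == 6.0
        assert list(log["method"]) == ["baseline"]

    def test_mode_fill_for_categorical(self):
        df = pd.DataFrame({"subject_id": [1, 2, 3, 4],
                           "smoker": [1.0, 0.0, 0.0, np.nan]})
        out, _ = simple_impute(df, baseline_cols=["smoker"])
        assert out["smoker"].iloc[3] == 0.0

    def test_locf_for_time_varying(self):
        df = pd.DataFrame({
            "subject_id": [1, 1, 1, 2], "k": [0, 1, 2, 0],
            "smoker": [0.0, 1.0, np.nan, 0.0],
        })
        out, log = simple_impute(df, timevarying_cols=["smoker"],
                                 subject_col="subject_id", order_col="k")
        assert out.loc[2, "smoker"] == 1.0
        assert set(log["method"]) == {"locf"}

    def test_fully_missing_column_raises(self):
        df = pd.DataFrame({"subject_id": [1, 2], "hba1c": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            simple_impute(df, baseline_cols=["hba1c"])


def _tiny_cohort():
    """8 subjects, 2 covariates; exposure split so both logistic fits exist."""
    return pd.DataFrame({
        "subject_id": range(8),
        "baseline_anemia": [1, 0, 0, 1, 0, 1, 0, 0],
        "z1": [0.5, -1.0, 0.8, 1.5, -0.3, -0.6, -1.2, 1.1],
        "z2": [1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0],
    })


class TestBaselineIpw:
    def test_matches_brute_force_logistic_oracle(self):
        df = _tiny_cohort()
        spec = WeightModelSpec(baseline_denominator=["z1", "z2"])
        sw, _ = fit_baseline_ipw(df, spec)

        a = df["baseline_anemia"].to_numpy(float)
        X = np.column_stack([np.ones(8), df["z1"], df["z2"]])

        def nll(beta, X_):
            eta = X_ @ beta
            return -np.sum(a * eta - np.log1p(np.exp(eta)))

        bd = optimize.minimize(nll, np.zeros(3), args=(X,), method="BFGS",
                               options={"gtol": 1e-12}).x
        bn = optimize.minimize(lambda b: nll(b, np.ones((8, 1))), [0.0],
                               method="BFGS", options={"gtol": 1e-12}).x
        p_d = 1 / (1 + np.exp(-(X @ bd)))
        p_n = np.full(8, 1 / (1 + np.exp(-bn[0])))
        expect = np.where(a == 1, p_n / p_d, (1 - p_n) / (1 - p_d))
        assert np.allclose(sw.to_numpy(), expect, atol=1e-6)

    def test_weights_go_to_one_without_confounding(self):
        rng = np.random.default_rng(0)
        n = 10000
        df = pd.DataFrame({
            "subject_id": range(n),
            "baseline_anemia": rng.binomial(1, 0.3, n),
            "z1": rng.normal(0, 1, n),
        })
        spec = WeightModelSpec(baseline_denominator=["z1"])
        sw, diag = fit_baseline_ipw(df, spec)
        assert abs(sw.mean() - 1) < 0.02
        assert np.quantile(np.abs(sw - 1), 0.95) < 0.1

    def test_constant_exposure_reports_separation(self):
        from msm_anemia.weights import SeparationError

        df = _tiny_cohort().assign(baseline_anemia=1)
        with pytest.raises(SeparationError):
            fit_baseline_ipw(df, WeightModelSpec(baseline_denominator=["z1"]))


@pytest.fixture(scope="module")
def weighted_panel(analysis_small):
    pp = analysis_small["pp"]
    spec = WeightModelSpec(denominator=["egfr_lag", "treatment_lag"],
                           baseline_denominator=["egfr", "age", "female"])
    return fit_time_varying_ipw(pp, spec)


class TestTimeVaryingIpw:
    def test_running_product_identity(self, weighted_panel):
        pp, _ = weighted_panel
        got = pp.groupby("subject_id", sort=False)["sw_period"].cumprod()
        assert np.allclose(pp["sw"], got)

    def test_mean_stabilized_weight_near_one_each_period(self, weighted_panel):
        pp, diag = weighted_panel
        by_k = diag["mean_weight_by_period"]
        assert (np.abs(by_k - 1) < 0.1).all()

    def test_identical_numerator_denominator_gives_exact_ones(self, analysis_small):
        pp = analysis_small["pp"]
        spec = WeightModelSpec(
            denominator=["egfr_lag"], numerator=["egfr_lag"],
            baseline_denominator=["egfr"], baseline_numerator=["egfr"],
        )
        out, _ = fit_time_varying_ipw(pp, spec)
        assert np.allclose(out["sw"], 1.0)

    def test_single_period_reduces_to_baseline_ipw(self, analysis_small):
        pp = analysis_small["pp"]
        first = pp[pp["k"] == 0].copy()
        spec = WeightModelSpec(denominator=["egfr_lag"],
                               baseline_denominator=["egfr", "age", "female"])
        out, _ = fit_time_varying_ipw(first, spec)
        sw_b, _ = fit_baseline_ipw(first, spec, exposure="anemia")
        assert np.allclose(np.sort(out["sw"].to_numpy()),
                           np.sort(sw_b.to_numpy()))

    def test_weighting_balances_confounders(self):
        """Within each period and exposure-history stratum, IPW drives the
        confounder-exposure standardized difference below the 0.1 balance
        criterion (stabilized weights balance conditionally on the
        numerator's exposure history, so balance is assessed per stratum)."""
        from msm_anemia import (SimulationConfig, build_cohort,
                                build_person_periods, simulate_cohort,
                                standardized_mean_difference)
        from msm_anemia.report import _with_egfr

        ck, cl, enr, _ = simulate_cohort(SimulationConfig(n_subjects=8000,
                                                          seed=11))
        cohort, _ = build_cohort(ck, cl, enr)
        cohort["female"] = (cohort["sex"] == "F").astype(int)
        pp = build_person_periods(cohort, _with_egfr(ck, enr), cl)
        spec = WeightModelSpec(denominator=["egfr_lag", "treatment_lag"],
                               baseline_denominator=["egfr", "age", "female"])
        pp, _ = fit_time_varying_ipw(pp, spec)
        for k in (1, 2, 3, 4):
            s = pp[(pp["k"] == k) & (pp["anemia_lag"] == 0.0)]
            raw = standardized_mean_difference(s, ["egfr_lag"], "anemia")
            bal = standardized_mean_difference(
                s, ["egfr_lag"], "anemia", weights=s["sw_period"])
            assert bal["egfr_lag"] < raw["egfr_lag"]
            assert bal["egfr_lag"] < 0.1


class TestTruncateWeights:
    def test_constant_weights_unchanged(self):
        w = np.full(50, 1.3)
        assert np.allclose(truncate_weights(w), w)

    def test_percentile_oracle_1_to_100(self):
        w = np.arange(1.0, 101.0)
        out = truncate_weights(w, 1, 99)
        lo, hi = np.percentile(w, [1, 99])  # linear interpolation
        assert out.max() == hi and out.min() == lo
        inner = (w > lo) & (w < hi)
        assert np.array_equal(out[inner], w[inner])

    def test_variance_contracts_and_order_preserved(self):
        rng = np.random.default_rng(3)
        w = rng.lognormal(0, 1, 500)
        out = truncate_weights(w, 5, 95)
        assert out.var() <= w.var()
        assert (np.diff(out[np.argsort(w)]) >= 0).all()

    def test_bad_percentiles_raise(self):
        with pytest.raises(ValueError):
            truncate_weights(np.ones(5), 99, 1)


class TestQuintileWeights:
    def test_equal_cells_within_sex(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "sex": ["M"] * 500 + ["F"] * 250,
            "baseline_hb": np.concatenate([rng.normal(15, 1.3, 500),
                                           rng.normal(13, 1.2, 250)]),
        })
        q = assign_hb_quintiles(df)
        counts = df.assign(q=q).groupby(["sex", "q"]).size()
        assert set(counts.loc["M"]) == {100} and set(counts.loc["F"]) == {50}

    def test_probabilities_sum_to_one_and_two_level_matches_binary(self, analysis_small):
        pp = analysis_small["pp"].copy()
        # two-category degenerate exposure: anemia as "quintile" {1,2}
        pp["hb_quintile"] = (pp["anemia"] + 1).astype(int)
        pp["hb_quintile_lag"] = (pp["anemia_lag"] + 1).astype(int)
        spec = WeightModelSpec(denominator=["egfr_lag"],
                               baseline_denominator=["egfr"])
        out_mn = fit_quintile_weights(pp, spec)
        out_bin, _ = fit_time_varying_ipw(pp, spec)
        assert np.allclose(out_mn["sw"].to_numpy(),
                           out_bin["sw"].to_numpy(), rtol=1e-4, atol=1e-6)
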