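"""Correlations, logistic fits, pseudo-R^2 and the 22-model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from expocube.models import (
    COMPARISON_KEYS,
    ECEI_KEYS,
    correlate_measures,
    fit_logit,
    nagelkerke_r2,
    overweight_from_bmi,
    run_comparison,
)


def newton_logit(X: np.ndarray, y: np.ndarray, iters=60) -> np.ndarray:
    """Independent Newton-Raphson logistic MLE (oracle, no statsmodels)."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        p = 1.0 / (1.0 + np.exp(-X @ beta))
        W = p * (1 - p)
        H = X.T @ (X * W[:, None])
        g = X.T @ (y - p)
        beta = beta + np.linalg.solve(H, g)
    return beta


def simulate(n, beta_exp=1.5, intercept=-1.0, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    cov = pd.DataFrame({
        "gender": rng.choice(["male", "female"], size=n),
        "age_group": rng.choice(["18-30", "31-65", "65+"], size=n,
                                p=[0.55, 0.4, 0.05]),
        "education": rng.choice(["college", "lt_college"], size=n),
    })
    eta = intercept + beta_exp * z + 0.5 * (cov["gender"] == "female")
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.Series(z), cov, y


class TestCorrelations:
    def test_column_against_itself_is_one(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 5.0, 7.0]})
        out = correlate_measures(df)
        row = out[(out.measure_a == "a") & (out.measure_b == "a")]
        assert row["r"].iloc[0] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = correlate_measures(pd.DataFrame({"x": x, "y": -x}))
        row = out[(out.measure_a == "x") & (out.measure_b == "y")]
        assert row["r"].iloc[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(50)
        x, y = rng.normal(size=46), rng.normal(size=46)
        out = correlate_measures(pd.DataFrame({"x": x, "y": y}))
        row = out[(out.measure_a == "x") & (out.measure_b == "y")]
        # direct formula oracle
        r_direct = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum()))
        assert row["r"].iloc[0] == pytest.approx(r_direct, rel=1e-12)

    def test_constant_column_reported_missing(self):
        out = correlate_measures(pd.DataFrame({"x": [1.0, 2.0, 3.0],
                                               "c": [5.0, 5.0, 5.0]}))
        row = out[(out.measure_a == "x") & (out.measure_b == "c")]
        assert np.isnan(row["r"].iloc[0])


class TestFitLogit:
    def test_coefficients_match_newton_oracle(self):
        z, cov, y = simulate(400, seed=51)
        res = fit_logit(z, cov, y, model_key="demo")
        X = np.column_stack([
            np.ones(len(y)), z,
            (cov["gender"] == "female").astype(float),
            (cov["age_group"] == "31-65").astype(float),
            (cov["age_group"] == "65+").astype(float),
            (cov["education"] == "college").astype(float),
        ])
        beta = newton_logit(X, y.to_numpy() if hasattr(y, "to_numpy") else y)
        np.testing.assert_allclose(res.coefficients["coef"].to_numpy(), beta,
                                   rtol=1e-6)

    def test_aic_identity_and_lr_nonnegative(self):
        z, cov, y = simulate(300, seed=52)
        res = fit_logit(z, cov, y)
        k = len(res.coefficients)
        assert res.aic == pytest.approx(2 * k - 2 * res.loglik)
        assert res.lr_chi2 >= 0.0
        assert res.lr_chi2 == pytest.approx(
            2 * (res.loglik - res.loglik_null), abs=1e-9)

    def test_nagelkerke_null_model_is_zero(self):
        # exposure carrying no information on a balanced response
        n = 200
        y = np.repeat([0, 1], n // 2)
        ll = n * np.log(0.5)
        assert nagelkerke_r2(ll, ll, n) == 0.0

    def test_nagelkerke_bounded(self):
        z, cov, y = simulate(300, beta_exp=3.0, seed=53)
        res = fit_logit(z, cov, y)
        assert 0.0 <= res.nagelkerke_r2 <= 1.0

    def test_odds_ratio_and_wald_ci(self):
        z, cov, y = simulate(500, seed=54)
        res = fit_logit(z, cov, y)
        b = res.coefficients.loc["exposure", "coef"]
        se = res.coefficients.loc["exposure", "se"]
        assert res.or_exposure == pytest.approx(np.exp(b))
        assert res.or_ci[0] == pytest.approx(np.exp(b - 1.96 * se))
        assert res.or_ci[1] == pytest.approx(np.exp(b + 1.96 * se))

    def test_perfect_separation_flagged_without_or(self):
        n = 60
        z = np.linspace(-2, 2, n)
        y = (z > 0).astype(int)
        cov = pd.DataFrame({"gender": ["male"] * n, "age_group": ["18-30"] * n,
                            "education": ["college"] * n})
        with pytest.warns(UserWarning):
            res = fit_logit(pd.Series(z), cov, y)
        assert res.separation
        assert res.or_exposure is None

    def test_covariates_null_flag(self):
        z, cov, y = simulate(300, seed=55)
        full = fit_logit(z, cov, y, null_model="intercept")
        part = fit_logit(z, cov, y, null_model="covariates")
        assert part.lr_df == 1
        assert part.lr_chi2 <= full.lr_chi2 + 1e-9

    def test_permuting_rows_leaves_fit_unchanged(self):
        z, cov, y = simulate(200, seed=56)
        res = fit_logit(z, cov, y)
        rng = np.random.default_rng(0)
        perm = rng.permutation(200)
        res_p = fit_logit(z.iloc[perm].reset_index(drop=True),
                          cov.iloc[perm].reset_index(drop=True), y[perm])
        np.testing.assert_allclose(res_p.coefficients["coef"],
                                   res.coefficients["coef"], rtol=1e-9)
        assert res_p.aic == pytest.approx(res.aic, rel=1e-12)


def _exposure_table(n=46, seed=57):
    rng = np.random.default_rng(seed)
    pids = [f"P{k:03d}" for k in range(n)]
    rows = []
    for key in ECEI_KEYS + COMPARISON_KEYS:
        z = rng.normal(size=n)
        z = (z - z.mean()) / z.std(ddof=1)
        for pid, v in zip(pids, z):
            rows.append({"participant_id": pid, "method_key": key, "ecei_z": v})
    return pd.DataFrame(rows), pids


def _participants(pids, seed=58):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "participant_id": pids,
        "gender": rng.choice(["male", "female"], size=len(pids)),
        "age_group": rng.choice(["18-30", "31-65"], size=len(pids)),
        "education": rng.choice(["college", "lt_college"], size=len(pids)),
        "overweight": rng.integers(0, 2, size=len(pids)),
    })


class TestRunComparison:
    def test_exactly_22_models_18_of_them_ecei(self):
        exp, pids = _exposure_table()
        table = run_comparison(exp, _participants(pids))
        assert len(table) == 22
        assert (table["kind"] == "ECEI").sum() == 18
        assert (table["kind"] == "comparison").sum() == 4
        assert list(table["aic_rank"]) == list(range(1, 23))
        assert table["aic"].is_monotonic_increasing

    def test_missing_method_column_fatal_and_named(self):
        exp, pids = _exposure_table()
        exp = exp[exp["method_key"] != "NEDD150T30"]
        with pytest.raises(ValueError, match="NEDD150T30"):
            run_comparison(exp, _participants(pids))

    def test_bmi_dichotomized_at_25(self):
        assert list(overweight_from_bmi([24.9, 25.0, 31.2])) == [0, 1, 1]

    def test_null_exposure_false_positive_rate_near_alpha(self):
        """With no true effect, ~5% of the 22 models flag exposure at p<0.05."""
        rng = np.random.default_rng(59)
        n_sig, n_tot = 0, 0
        for rep in range(12):
            exp, pids = _exposure_table(seed=100 + rep)
            table = run_comparison(exp, _participants(pids, seed=200 + rep))
            n_sig += int((table["exposure_p"] < 0.05).sum())
            n_tot += len(table)
        rate = n_sig / n_tot
        # 264 fits: expect ~5%; generous 3-sigma band for correlated draws
        assert rate < 0.12


class TestParameterRecovery:
    def test_known_coefficients_recovered_at_n_2000(self):
        z, cov, y = simulate(2000, beta_exp=1.5, intercept=-1.0, seed=60)
        res = fit_logit(z, cov, y)
        b = res.coefficients.loc["exposure", "coef"]
        se = res.coefficients.loc["exposure", "se"]
        assert abs(b - 1.5) < 3 * se
        b0 = res.coefficients.loc["const", "coef"]
        se0 = res.coefficients.loc["const", "se"]
        assert abs(b0 - (-1.0)) < 3 * se0
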