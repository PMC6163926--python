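"""Logistic model harness: correlations, 22-model comparison, fit metrics.

Each exposure measure (18 cube-based ECEI keys x {KD, ISDD, NEDD} x
{100, 150, 200 m} x {10, 30 min}, plus the four static measures M-GTB,
M-MCP, M-SDE1, M-SDE2) enters its own binary logistic regression of
overweight status (BMI >= 25 kg/m^2) on the z-scored exposure, adjusted
for gender (male reference), age band (18-30 reference; 31-65, 65+) and
education (below college reference).  Models are compared on AIC,
Nagelkerke pseudo-R^2 and the likelihood-ratio chi-square against the
intercept-only null; the exposure effect is reported as an odds ratio
with a 95% Wald interval.  No multiple-testing correction is applied
across the 22 models — the comparison is descriptive, and raw p-values
are reported.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

AGE_BANDS = ("18-30", "31-65", "65+")
OVERWEIGHT_BMI_CUTOFF = 25.0

#: The 18 cube-based exposure keys plus the 4 static comparators.
ECEI_KEYS = tuple(
    f"{m}{s}T{t}" for m in ("KD", "ISDD", "NEDD") for s in (100, 150, 200)
    for t in (10, 30)
)
COMPARISON_KEYS = ("M-GTB", "M-MCP", "M-SDE1", "M-SDE2")


@dataclass
class ModelResult:
    model_key: str
    n: int
    aic: float
    loglik: float
    loglik_null: float
    nagelkerke_r2: float
    lr_chi2: float
    lr_df: int
    lr_p: float
    coefficients: pd.DataFrame  # index: term; columns: coef, se, p
    or_exposure: float | None
    or_ci: tuple[float, float] | None
    separation: bool = False
    notes: list = field(default_factory=list)


def overweight_from_bmi(bmi) -> np.ndarray:
    """1 if BMI >= 25.0 kg/m^2 (overweight or obese), else 0."""
    return (np.asarray(bmi, dtype=float) >= OVERWEIGHT_BMI_CUTOFF).astype(int)


def design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Covariate dummies with the reference levels dropped.

    gender: female indicator (male reference); age_group: 31-65 and 65+
    indicators (18-30 reference); education: college-degree-or-higher
    indicator (below-college reference).  All-zero columns (empty
    categories in small cohorts) are dropped with a warning.
    """
    X = pd.DataFrame(index=covariates.index)
    X["female"] = (covariates["gender"] == "female").astype(float)
    X["age_31_65"] = (covariates["age_group"] == "31-65").astype(float)
    X["age_65plus"] = (covariates["age_group"] == "65+").astype(float)
    X["college"] = (covariates["education"] == "college").astype(float)
    empty = [c for c in X.columns if X[c].nunique() <= 1]
    if empty:
        warnings.warn(f"dropping constant covariate column(s): {empty}")
        X = X.drop(columns=empty)
    return X


def correlate_measures(exposures: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r and two-sided p between exposure measures.

    ``exposures`` is wide: one row per participant, one column per
    method key.  Constant columns yield missing correlations.
    """
    cols = list(exposures.columns)
    rows = []
    for a, b in itertools.combinations_with_replacement(cols, 2):
        x, y = exposures[a].to_numpy(), exposures[b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, y)
        rows.append({"measure_a": a, "measure_b": b, "r": r, "p": p})
    return pd.DataFrame(rows)


def nagelkerke_r2(loglik: float, loglik_null: float, n: int) -> float:
    """Nagelkerke rescaled Cox-Snell pseudo-R^2, bounded on [0, 1]."""
    cox_snell = 1.0 - np.exp(2.0 / n * (loglik_null - loglik))
    max_cs = 1.0 - np.exp(2.0 / n * loglik_null)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def fit_logit(exposure_z: pd.Series | np.ndarray, covariates: pd.DataFrame,
              overweight: pd.Series | np.ndarray,
              model_key: str = "model",
              null_model: str = "intercept") -> ModelResult:
    """One adjusted binary logistic regression of overweight on exposure.

    The likelihood-ratio chi-square compares the full model against the
    intercept-only null by default (``null_model="intercept"``), measuring
    the whole model; ``null_model="covariates"`` tests the exposure term
    alone against the covariate-adjusted null.  Perfect or quasi-perfect
    separation is flagged (``separation=True``) and the odds ratio withheld.
    """
    y = np.asarray(overweight, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("overweight must be binary 0/1")
    Xcov = design_matrix(covariates).reset_index(drop=True)
    X = pd.concat(
        [pd.Series(np.asarray(exposure_z, dtype=float), name="exposure"), Xcov],
        axis=1,
    )
    X = sm.add_constant(X, prepend=True)
    n = len(y)

    notes: list[str] = []

    def _fit(design):
        try:
            return sm.Logit(y, design).fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # singular Hessian: (quasi-)separated fit; BFGS still yields a
            # usable log-likelihood so the result can be flagged, not lost
            f = sm.Logit(y, design).fit(disp=0, maxiter=500, method="bfgs")
            f.mle_retvals["converged"] = False
            return f

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = _fit(X)
        # a quasi-separated nuisance dummy (e.g. a near-empty age band)
        # diverges without informing the exposure effect: drop and refit
        bad = [t for t in fit.params.index
               if t not in ("const", "exposure")
               and (abs(fit.params[t]) > 20 or fit.bse[t] > 100)]
        if bad:
            notes.extend(f"dropped quasi-separated term: {t}" for t in bad)
            Xcov = Xcov.drop(columns=bad)
            X = X.drop(columns=bad)
            fit = _fit(X)
        null_fit = sm.Logit(y, np.ones((n, 1))).fit(disp=0, maxiter=200)
        if null_model == "covariates":
            null_fit = sm.Logit(
                y, sm.add_constant(Xcov, prepend=True)
            ).fit(disp=0, maxiter=200)
        elif null_model != "intercept":
            raise ValueError("null_model must be 'intercept' or 'covariates'")

    # separation is flagged on the exposure term (the reported effect);
    # a quasi-separated nuisance dummy (e.g. a near-empty age band) only
    # earns a note, as its huge SE does not invalidate the exposure OR
    separation = (
        not fit.mle_retvals.get("converged", True)
        or abs(fit.params["exposure"]) > 20
        or fit.bse["exposure"] > 100
    )
    coeffs = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "p": fit.pvalues}
    )
    lr_chi2 = max(2.0 * (fit.llf - null_fit.llf), 0.0)
    lr_df = int(X.shape[1] - (1 if null_model == "intercept" else Xcov.shape[1] + 1))
    lr_p = float(stats.chi2.sf(lr_chi2, lr_df)) if lr_df > 0 else np.nan

    if separation:
        or_exposure, or_ci = None, None
    else:
        b, se = fit.params["exposure"], fit.bse["exposure"]
        or_exposure = float(np.exp(b))
        or_ci = (float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se)))

    # Nagelkerke is conventionally reported against the intercept-only null.
    ll0 = null_fit.llf if null_model == "intercept" else sm.Logit(
        y, np.ones((n, 1))
    ).fit(disp=0, maxiter=200).llf

    return ModelResult(
        model_key=model_key,
        n=n,
        aic=float(fit.aic),
        loglik=float(fit.llf),
        loglik_null=float(ll0),
        nagelkerke_r2=nagelkerke_r2(fit.llf, ll0, n),
        lr_chi2=float(lr_chi2),
        lr_df=lr_df,
        lr_p=lr_p,
        coefficients=coeffs,
        or_exposure=or_exposure,
        or_ci=or_ci,
        separation=separation,
        notes=notes,
    )


def run_comparison(exposures: pd.DataFrame, participants: pd.DataFrame,
                   null_model: str = "intercept") -> pd.DataFrame:
    """Fit the full 22-model comparison and rank by AIC.

    ``exposures`` is tidy (participant_id, method_key, ecei_z) and must
    contain all 18 cube-based keys and the 4 static keys; ``participants``
    carries participant_id, gender, age_group, education and either an
    ``overweight`` flag or a ``bmi`` column.  Returns one row per model
    with AIC, Nagelkerke R^2, LR chi-square and the exposure odds ratio,
    sorted by AIC (best first) with an ``aic_rank`` column.
    """
    wide = exposures.pivot(index="participant_id", columns="method_key",
                           values="ecei_z")
    missing = [k for k in ECEI_KEYS + COMPARISON_KEYS if k not in wide.columns]
    if missing:
        raise ValueError(f"missing exposure method column(s): {missing}")

    part = participants.set_index("participant_id").loc[wide.index]
    if "overweight" in part.columns:
        y = part["overweight"].to_numpy(dtype=float)
    elif "bmi" in part.columns:
        y = overweight_from_bmi(part["bmi"])
    else:
        raise ValueError("participants need an 'overweight' or 'bmi' column")
    cov = part[["gender", "age_group", "education"]].reset_index(drop=True)

    rows = []
    results: dict[str, ModelResult] = {}
    for key in ECEI_KEYS + COMPARISON_KEYS:
        res = fit_logit(wide[key].reset_index(drop=True), cov, y,
                        model_key=key, null_model=null_model)
        results[key] = res
        rows.append(
            {
                "model_key": key,
                "kind": "ECEI" if key in ECEI_KEYS else "comparison",
                "n": res.n,
                "aic": res.aic,
                "nagelkerke_r2": res.nagelkerke_r2,
                "lr_chi2": res.lr_chi2,
                "lr_p": res.lr_p,
                "or_exposure": res.or_exposure,
                "or_ci_low": res.or_ci[0] if res.or_ci else np.nan,
                "or_ci_high": res.or_ci[1] if res.or_ci else np.nan,
                "exposure_p": res.coefficients.loc["exposure", "p"],
                "separation": res.separation,
            }
        )
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    table["aic_rank"] = np.arange(1, len(table) + 1)
    table.attrs["results"] = results
    return table


def report_markdown(table: pd.DataFrame) -> str:
    """Appendix-style Markdown report of the ranked model comparison."""
    lines = [
        "| rank | model | AIC | Nagelkerke R2 | LR chi2 | LR p | OR (95% CI) | p(exposure) |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for _, row in table.iterrows():
        if row["separation"] or pd.isna(row["or_exposure"]):
            or_txt = "— (separation)" if row["separation"] else "—"
        else:
            or_txt = (
                f"{row['or_exposure']:.2f} "
                f"({row['or_ci_low']:.2f}, {row['or_ci_high']:.2f})"
            )
        lines.append(
            f"| {int(row['aic_rank'])} | {row['model_key']} | {row['aic']:.3f} "
            f"| {row['nagelkerke_r2']:.4f} | {row['lr_chi2']:.3f} "
            f"| {row['lr_p']:.4g} | {or_txt} | {row['exposure_p']:.4g} |"
        )
    return "\n".join(lines)
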