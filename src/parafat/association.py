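"""Linear models relating fatty infiltration to pain and disability.

For each patient-reported outcome two predictors are compared: the
continuous MFI and the trichotomised Goutallier category (dummy-coded
against category 0, "no fatty infiltration").  Each is fitted univariately
and adjusted for age, sex, BMI and smoking status.  Model fit is compared by
the Akaike information criterion; the model with the lower AIC fits better.

AIC convention: −2·(maximised Gaussian log-likelihood, MLE variance RSS/n)
+ 2·(mean parameters + 1 for the residual variance).  Only AIC differences
within one outcome and case set are meaningful, and those are invariant to
the convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import OUTCOME_NAMES

MIN_COMPLETE_CASES = 10
ALPHA = 0.05

COVARIATES = ("age", "sex", "bmi", "smoking")
GCS_DUMMIES = ("gcs_cat_I", "gcs_cat_II")


@dataclass
class AssociationResult:
    """One fitted linear model: per-term estimates and the model AIC."""

    outcome: str
    predictor: str               # "mfi" or "gcs"
    adjusted: bool
    terms: pd.DataFrame          # index term; columns coef, ci_low, ci_high, p
    aic: float
    aic_defined: bool
    n_used: int
    n_dropped: int
    residuals: pd.DataFrame = field(repr=False, default=None)

    def significant_terms(self, alpha: float = ALPHA) -> list[str]:
        t = self.terms.drop(index="const", errors="ignore")
        return list(t.index[t["p"] < alpha])


@dataclass(frozen=True)
class AicComparison:
    """Verdict on an AIC difference, delta = AIC(B) − AIC(A)."""

    aic_a: float
    aic_b: float
    delta: float
    verdict: str                 # equivalent | negligible | meaningful | strong
    better: str                  # name of the lower-AIC model ("tie" at 0)
    label_a: str = "A"
    label_b: str = "B"


def _design_matrix(df: pd.DataFrame, predictor: str, adjusted: bool) -> pd.DataFrame:
    if predictor == "mfi":
        X = df[["mfi_selected"]].rename(columns={"mfi_selected": "mfi"})
    elif predictor == "gcs":
        cat = df["gcs_category"].astype(str)
        X = pd.DataFrame(
            {
                "gcs_cat_I": (cat == "I").astype(float),
                "gcs_cat_II": (cat == "II").astype(float),
            },
            index=df.index,
        )
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    if adjusted:
        X = pd.concat([X, df[list(COVARIATES)].astype(float)], axis=1)
    return sm.add_constant(X, has_constant="add")


def gaussian_aic(llf: float, n_mean_params: int) -> float:
    """AIC with the residual variance counted as a fitted parameter."""
    return -2.0 * llf + 2.0 * (n_mean_params + 1)


def fit_linear(
    cohort: pd.DataFrame,
    outcome: str,
    predictor: str = "mfi",
    adjusted: bool = False,
    min_cases: int = MIN_COMPLETE_CASES,
) -> AssociationResult:
    """Ordinary least squares of one outcome on one predictor.

    Listwise deletion handles missing values (the dropped count is
    reported).  Coefficients come with t-based 95% CIs and two-sided
    p-values.  A perfect fit (zero residual variance) returns coefficients
    but flags the AIC as undefined.
    """
    needed = [outcome, "mfi_selected" if predictor == "mfi" else "gcs_category"]
    if adjusted:
        needed += list(COVARIATES)
    data = cohort[needed].dropna()
    n_dropped = len(cohort) - len(data)
    if len(data) < min_cases:
        raise ValueError(
            f"only {len(data)} complete cases for {outcome} ~ {predictor}; "
            f"need at least {min_cases}"
        )

    y = data[outcome].astype(float)
    X = _design_matrix(data, predictor, adjusted)
    pred_cols = [c for c in X.columns if c != "const"]
    for col in pred_cols:
        if X[col].nunique() <= 1:
            raise ValueError(f"predictor term {col!r} has no variation")

    res = sm.OLS(y, X).fit()

    ci = res.conf_int(alpha=ALPHA)
    terms = pd.DataFrame(
        {
            "coef": res.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": res.pvalues,
        }
    )

    # llf is the Gaussian log-likelihood at the MLE variance RSS/n; a
    # numerically perfect fit leaves it (and the AIC) undefined
    rss = float(res.ssr)
    tss = float(((y - y.mean()) ** 2).sum())
    aic_defined = rss > max(tss, 1.0) * 1e-12 and np.isfinite(res.llf)
    aic = gaussian_aic(float(res.llf), len(res.params)) if aic_defined else float("nan")

    sigma = np.sqrt(rss / len(y)) if aic_defined else 0.0
    residuals = pd.DataFrame(
        {
            "fitted": res.fittedvalues,
            "residual": res.resid,
            "standardized_residual": res.resid / sigma if sigma > 0 else res.resid * 0.0,
        }
    )
    return AssociationResult(
        outcome=outcome,
        predictor=predictor,
        adjusted=adjusted,
        terms=terms,
        aic=aic,
        aic_defined=aic_defined,
        n_used=len(data),
        n_dropped=n_dropped,
        residuals=residuals,
    )


def compare_aic(
    aic_a: float,
    aic_b: float,
    n_a: int | None = None,
    n_b: int | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> AicComparison:
    """Classify the difference between two AIC values on the same data.

    delta = AIC(B) − AIC(A).  |delta| = 0 → equivalent; 0 < |delta| < 2 →
    negligible; 2 ≤ |delta| < 6 → meaningful; |delta| ≥ 6 → strong.  The
    tiers reconcile the two common rules of thumb (2–7 units meaningful; at
    least 6 units for a decisive preference).
    """
    if not (np.isfinite(aic_a) and np.isfinite(aic_b)):
        raise ValueError("both AIC values must be finite")
    if n_a is not None and n_b is not None and n_a != n_b:
        raise ValueError(
            f"models were fitted on different case sets (n={n_a} vs n={n_b}); "
            "their AICs are not comparable"
        )
    delta = float(aic_b - aic_a)
    mag = abs(delta)
    if mag == 0:
        verdict = "equivalent"
    elif mag < 2:
        verdict = "negligible"
    elif mag < 6:
        verdict = "meaningful"
    else:
        verdict = "strong"
    better = "tie" if delta == 0 else (label_a if delta > 0 else label_b)
    return AicComparison(
        aic_a=float(aic_a), aic_b=float(aic_b), delta=delta,
        verdict=verdict, better=better, label_a=label_a, label_b=label_b,
    )


def run_association_suite(
    cohort: pd.DataFrame,
    outcomes: tuple[str, ...] = OUTCOME_NAMES,
    alpha: float = ALPHA,
) -> dict:
    """Fit all outcome × predictor × adjustment combinations.

    Returns a dict with ``results`` (list of AssociationResult for each of
    the outcomes crossed with {MFI, GCS} × {univariate, adjusted}),
    ``comparisons`` (AicComparison of the MFI model vs the GCS model per
    outcome and adjustment level), ``table`` (a flat frame of coefficients,
    CIs, p-values and AICs) and ``significance`` flags at the given alpha.
    """
    results: list[AssociationResult] = []
    comparisons: list[dict] = []
    rows = []
    for outcome in outcomes:
        for adjusted in (False, True):
            fits = {}
            for predictor in ("mfi", "gcs"):
                r = fit_linear(cohort, outcome, predictor, adjusted)
                fits[predictor] = r
                results.append(r)
                for term, vals in r.terms.iterrows():
                    if term == "const" or term in COVARIATES:
                        continue
                    rows.append(
                        {
                            "outcome": outcome,
                            "predictor": predictor,
                            "adjusted": adjusted,
                            "term": term,
                            "coef": vals["coef"],
                            "ci_low": vals["ci_low"],
                            "ci_high": vals["ci_high"],
                            "p": vals["p"],
                            "significant": bool(vals["p"] < alpha),
                            "aic": r.aic,
                            "n": r.n_used,
                        }
                    )
            cmp = compare_aic(
                fits["mfi"].aic, fits["gcs"].aic,
                fits["mfi"].n_used, fits["gcs"].n_used,
                label_a="mfi", label_b="gcs",
            )
            comparisons.append(
                {"outcome": outcome, "adjusted": adjusted, "comparison": cmp}
            )
    return {
        "results": results,
        "comparisons": comparisons,
        "table": pd.DataFrame(rows),
        "alpha": alpha,
    }
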