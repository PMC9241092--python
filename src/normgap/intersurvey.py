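"""Meta-analysis across survey scenarios: how gender-age sampling
distributions relate to (a) the odds of a significant interaction and
(b) the magnitude and direction of coefficient / relative-risk shifts.

With only a couple of dozen survey scenarios per pathway, predictors are
entered one at a time (simple regressions) by default; a joint fit exists
but warns about its fragility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import ConfigurationError, DataError, ModellingError

DEFAULT_PREDICTORS = ("adolescent_female_share", "adolescent_male_share", "male_share_total")
RECORD_COLUMNS = (
    "survey_id",
    "pathway",
    "adolescent_female_share",
    "adolescent_male_share",
    "male_share_total",
    "significant_interaction",
    "interaction_coef",
    "rr",
)


def _as_frame(records) -> pd.DataFrame:
    frame = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"inter-survey records missing columns: {missing}")
    for col in DEFAULT_PREDICTORS:
        vals = frame[col].astype(float)
        if ((vals < 0) | (vals > 1)).any():
            raise DataError(f"predictor {col!r} must be a proportion in [0, 1]")
    dup = frame.duplicated(subset=["survey_id", "pathway"])
    if dup.any():
        raise DataError("expected one record per survey x pathway")
    return frame


@dataclass
class InterSurveySummary:
    """Tidy per-(pathway, predictor) estimates.

    For logistic rows, ``estimate`` is the odds ratio per 1-percentage-
    point increase in the predictor; for linear rows it is the
    least-squares slope per 1-pp for the named outcome.
    """

    frame: pd.DataFrame
    kind: str  # "logistic" | "linear"


def fit_significance_logit(
    records, predictors=DEFAULT_PREDICTORS, min_records: int = 10
) -> InterSurveySummary:
    """Per-pathway logistic regression of interaction significance on each
    sampling-distribution predictor (entered one at a time).

    Constant outcomes are flagged ``inestimable``; complete separation is
    detected and flagged rather than raised.
    """
    frame = _as_frame(records)
    rows = []
    for pathway, grp in frame.groupby("pathway", sort=True):
        if len(grp) < min_records:
            raise DataError(
                f"pathway {pathway}: {len(grp)} records < required minimum {min_records}"
            )
        y = grp["significant_interaction"].astype(float).to_numpy()
        for pred in predictors:
            x_pp = grp[pred].astype(float).to_numpy() * 100.0  # percentage points
            row = {
                "pathway": pathway,
                "predictor": pred,
                "n": len(grp),
                "estimate": np.nan,
                "ci_lower": np.nan,
                "ci_upper": np.nan,
                "p_value": np.nan,
                "flag": "",
            }
            if y.min() == y.max():
                row["flag"] = "inestimable"
                rows.append(row)
                continue
            X = sm.add_constant(pd.DataFrame({pred: x_pp}))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
                    beta = float(res.params[pred])
                    se = float(res.bse[pred])
                    if not np.isfinite(se) or abs(beta) > 15 or se > 50:
                        row["flag"] = "separation"
                    else:
                        row["estimate"] = float(np.exp(beta))
                        row["ci_lower"] = float(np.exp(beta - 1.96 * se))
                        row["ci_upper"] = float(np.exp(beta + 1.96 * se))
                        row["p_value"] = float(2.0 * stats.norm.sf(abs(beta / se)))
                except Exception:
                    row["flag"] = "separation"
            rows.append(row)
    return InterSurveySummary(pd.DataFrame(rows), "logistic")


def fit_outcome_linear(
    records,
    predictors=DEFAULT_PREDICTORS,
    outcomes=("interaction_coef", "rr"),
    min_records: int = 10,
) -> InterSurveySummary:
    """Per-pathway least-squares slopes of the continuous model outcomes
    on each sampling-distribution predictor (per 1 percentage point)."""
    frame = _as_frame(records)
    rows = []
    for pathway, grp in frame.groupby("pathway", sort=True):
        if len(grp) < min_records:
            raise DataError(
                f"pathway {pathway}: {len(grp)} records < required minimum {min_records}"
            )
        for pred in predictors:
            x_pp = grp[pred].astype(float).to_numpy() * 100.0
            if np.ptp(x_pp) == 0:
                raise ModellingError(f"predictor {pred!r} has zero variance")
            X = sm.add_constant(pd.DataFrame({pred: x_pp}))
            for outcome in outcomes:
                y = grp[outcome].astype(float).to_numpy()
                res = sm.OLS(y, X).fit()
                beta = float(res.params[pred])
                se = float(res.bse[pred])
                rows.append(
                    {
                        "pathway": pathway,
                        "predictor": pred,
                        "outcome": outcome,
                        "n": len(grp),
                        "estimate": beta,
                        "ci_lower": beta - 1.96 * se,
                        "ci_upper": beta + 1.96 * se,
                        "p_value": float(res.pvalues[pred]),
                        "flag": "",
                    }
                )
    return InterSurveySummary(pd.DataFrame(rows), "linear")


def fit_joint_logit(records, predictors=DEFAULT_PREDICTORS) -> InterSurveySummary:
    """Joint logistic fit of all predictors at once.  Warns: a handful of
    survey scenarios cannot support a joint model."""
    warnings.warn(
        "joint inter-survey fits are fragile at these sample sizes; "
        "prefer the one-at-a-time summaries",
        stacklevel=2,
    )
    frame = _as_frame(records)
    rows = []
    for pathway, grp in frame.groupby("pathway", sort=True):
        y = grp["significant_interaction"].astype(float).to_numpy()
        X = sm.add_constant(grp[list(predictors)].astype(float) * 100.0)
        if y.min() == y.max():
            for pred in predictors:
                rows.append({"pathway": pathway, "predictor": pred, "n": len(grp),
                             "estimate": np.nan, "ci_lower": np.nan, "ci_upper": np.nan,
                             "p_value": np.nan, "flag": "inestimable"})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        for pred in predictors:
            beta, se = float(res.params[pred]), float(res.bse[pred])
            rows.append(
                {
                    "pathway": pathway,
                    "predictor": pred,
                    "n": len(grp),
                    "estimate": float(np.exp(beta)),
                    "ci_lower": float(np.exp(beta - 1.96 * se)),
                    "ci_upper": float(np.exp(beta + 1.96 * se)),
                    "p_value": float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan,
                    "flag": "joint",
                }
            )
    return InterSurveySummary(pd.DataFrame(rows), "logistic")
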