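"""Stabilized inverse-probability weights: treatment, adherence, LTFU.

Treatment (baseline) weights: denominator is a logistic model of initiation
on the baseline adjustment set; numerator is the marginal initiation
probability; the stabilized weight is P(A=a)/P(A=a|L), mean ≈ 1.

Censoring weights (adherence = remaining free of protocol deviation; LTFU =
remaining enrolled) are fit on person-months, separately by strategy, as
pooled logistic models of remaining uncensored in month m.  The stabilized
numerator model uses baseline covariates plus month and month²; the
denominator adds the time-varying covariates.  The weight at month m is the
cumulative product over months k ≤ m of numerator/denominator probabilities
of remaining uncensored — non-anticipating given fitted monthly
probabilities.

All weights are truncated at a configurable percentile (default 99, linear
interpolation quantile).  Adherence and LTFU weights are each truncated
before being multiplied into a combined weight.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._glm import fit_logistic
from .errors import DataError, EstimationError

#: The baseline adjustment set used throughout the emulation.
BASELINE_ADJUSTMENT = ("age", "race_ethnicity", "marital_status",
                       "education_quartile", "charlson", "base_diabetes",
                       "base_chf", "base_cerebrovascular", "base_hypertension",
                       "base_depression", "pcp_visits")

#: Same set, as named on the one-row-per-subject cohort table.
BASELINE_ADJUSTMENT_COHORT = ("age", "race_ethnicity", "marital_status",
                              "education_quartile", "charlson", "diabetes",
                              "chf", "cerebrovascular", "hypertension",
                              "depression", "pcp_visits")

TIME_VARYING_ADJUSTMENT = ("diabetes", "chf", "cerebrovascular", "hypertension",
                           "depression", "contraindication_any")

# charlson enters adjustment models as a numeric score: its sparse top
# categories (a handful of subjects) otherwise quasi-separate the Cox fit,
# and when the toy score is an exact combination of the adjusted condition
# indicators the aliasing guard removes it
_CATEGORICAL = {"race_ethnicity", "marital_status", "education_quartile"}


@dataclasses.dataclass
class WeightSet:
    """Per-row weights with their fitting metadata."""

    scope: str                      # baseline_treatment | adherence | ltfu
    stabilized: pd.Series
    truncated: pd.Series
    truncation_percentile: float
    model_info: dict

    def diagnostics(self) -> dict:
        w = self.stabilized.to_numpy(dtype=float)
        t = self.truncated.to_numpy(dtype=float)
        qs = np.percentile(w, [1, 25, 50, 75, 99]) if len(w) else [np.nan] * 5
        return {
            "scope": self.scope,
            "n": int(len(w)),
            "mean": float(np.mean(w)) if len(w) else np.nan,
            "sd": float(np.std(w)) if len(w) else np.nan,
            "min": float(np.min(w)) if len(w) else np.nan,
            "max": float(np.max(w)) if len(w) else np.nan,
            "percentiles": {p: float(v) for p, v in zip([1, 25, 50, 75, 99], qs)},
            "pct_truncated": float(np.mean(t < w) * 100) if len(w) else np.nan,
            "truncation_percentile": self.truncation_percentile,
        }


def design_matrix(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Intercept + dummy-coded design for the given covariate names.

    Exactly aliased columns are dropped (first-come order kept), the way R
    and SAS silently alias redundant terms — e.g. a comorbidity-count
    category can be a linear combination of the individual condition
    indicators.
    """
    X = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    for cov in covariates:
        if cov in _CATEGORICAL:
            d = pd.get_dummies(df[cov].astype("category"), prefix=cov,
                               drop_first=True, dtype=float)
            X = pd.concat([X, d], axis=1)
        else:
            X[cov] = pd.to_numeric(df[cov], errors="raise").astype(float)
    return _drop_aliased(X)


def _drop_aliased(X: pd.DataFrame, tol: float = 1e-8) -> pd.DataFrame:
    """Keep a maximal left-to-right subset of linearly independent columns.

    Works on the Gram matrix, so cost is O(n k²) + O(k⁴) for k columns.
    """
    A = X.to_numpy(dtype=float)
    norms = np.linalg.norm(A, axis=0)
    nonzero = norms > 0
    A = np.where(nonzero, A / np.where(nonzero, norms, 1.0), 0.0)
    G = A.T @ A  # unit diagonal: resid2 is a squared sine of the angle
    keep: list[int] = []
    for j in range(A.shape[1]):
        if not nonzero[j]:
            continue
        if not keep:
            resid2 = 1.0
        else:
            sub = G[np.ix_(keep, keep)]
            cross = G[np.ix_(keep, [j])]
            coef = np.linalg.lstsq(sub, cross, rcond=None)[0]
            resid2 = 1.0 - (cross.T @ coef).item()
        if resid2 > tol:
            keep.append(j)
    return X.iloc[:, keep]


def _fit_logistic(y: np.ndarray, X: pd.DataFrame, context: str):
    return fit_logistic(y, X, context=context)


def truncate_weights(weights, percentile: float = 99.0) -> np.ndarray:
    """Cap weights at their empirical percentile (linear interpolation)."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise DataError("truncate_weights: empty weight vector")
    if not 0 < percentile <= 100:
        raise DataError("truncate_weights: percentile outside (0, 100]")
    cap = np.percentile(w, percentile)
    return np.minimum(w, cap)


def fit_treatment_weights(cohort: pd.DataFrame,
                          covariates=BASELINE_ADJUSTMENT_COHORT,
                          truncation_percentile: float = 99.0) -> WeightSet:
    """Stabilized baseline-treatment weights for the one-row-per-subject table."""
    a = cohort["initiator"].to_numpy(dtype=float)
    if a.min() == a.max():
        raise EstimationError("treatment weights: only one strategy present",
                              diagnostics={"n_initiators": int(a.sum())})
    marginal = a.mean()
    if len(covariates) == 0:
        p = np.full(len(cohort), marginal)
    else:
        X = design_matrix(cohort, covariates)
        res = _fit_logistic(a, X, "treatment weights")
        p = np.asarray(res.predict(X))
    num = np.where(a == 1, marginal, 1 - marginal)
    den = np.where(a == 1, p, 1 - p)
    w = pd.Series(num / den, index=cohort.index)
    model_info = {"covariates": list(covariates), "marginal": float(marginal),
                  "converged": True}
    if len(covariates):
        model_info["coefficients"] = res.params.to_dict()
    return WeightSet("baseline_treatment", w,
                     pd.Series(truncate_weights(w, truncation_percentile), index=w.index),
                     truncation_percentile, model_info)


def cumulative_ratio_weights(pm: pd.DataFrame, p_num: np.ndarray,
                             p_den: np.ndarray) -> pd.Series:
    """Cumulative product over months of numerator/denominator probabilities.

    ``p_num`` and ``p_den`` are per-row probabilities of remaining
    uncensored; rows must be grouped by patient in month order.  Censoring
    takes effect at month END (covariates and censoring risk are assessed
    at month start), so the weight for month m multiplies the ratios of
    months k < m — a subject contributes month m whenever uncensored
    through month m−1, and the weight for month 0 is 1.
    """
    ratio = np.asarray(p_num, dtype=float) / np.asarray(p_den, dtype=float)
    s = pd.Series(ratio, index=pm.index)
    ordered = pm.sort_values(["patient_id", "month"], kind="stable").index
    grouped = s.loc[ordered].groupby(pm["patient_id"].loc[ordered])
    lagged = grouped.cumprod() / s.loc[ordered]  # product over months < m
    return lagged.reindex(pm.index)


def _fit_censor_weights(pm: pd.DataFrame, censor_col: str, scope: str,
                        baseline_covariates, time_varying,
                        truncation_percentile: float) -> WeightSet:
    """Shared machinery for adherence and LTFU weights (fit per strategy)."""
    w = pd.Series(1.0, index=pm.index)
    info: dict = {"covariates": list(baseline_covariates),
                  "time_varying": list(time_varying), "by_strategy": {}}
    month_terms = ["month", "month_sq"]
    for strat, sub in pm.groupby("strategy"):
        c = sub[censor_col].to_numpy(dtype=float)
        if c.sum() == 0:
            # degenerate: nobody censored in this stratum; weights stay 1
            info["by_strategy"][strat] = {"n_censored": 0, "degenerate": True}
            continue
        y = 1.0 - c  # remaining uncensored this month
        Xd = design_matrix(sub, list(baseline_covariates) + list(time_varying))
        Xd[month_terms] = sub[month_terms].astype(float)
        Xn = design_matrix(sub, baseline_covariates)
        Xn[month_terms] = sub[month_terms].astype(float)
        ridge_used = 0.0
        try:
            den = _fit_logistic(y, Xd, f"{scope} weights ({strat}) denominator")
            num = _fit_logistic(y, Xn, f"{scope} weights ({strat}) numerator")
        except EstimationError:
            # sparse censoring events can quasi-separate the monthly model;
            # refit with a weakly informative L2 stabilizer
            ridge_used = 1.0
            den = fit_logistic(y, Xd, ridge=ridge_used,
                               context=f"{scope} weights ({strat}) denominator")
            num = fit_logistic(y, Xn, ridge=ridge_used,
                               context=f"{scope} weights ({strat}) numerator")
        w.loc[sub.index] = cumulative_ratio_weights(
            sub, np.asarray(num.predict(Xn)), np.asarray(den.predict(Xd)))
        info["by_strategy"][strat] = {
            "n_censored": int(c.sum()), "degenerate": False,
            "ridge": ridge_used,
            "den_coefficients": den.params.to_dict(),
            "num_coefficients": num.params.to_dict(),
        }
    return WeightSet(scope, w,
                     pd.Series(truncate_weights(w, truncation_percentile), index=w.index),
                     truncation_percentile, info)


def fit_adherence_weights(pm: pd.DataFrame,
                          baseline_covariates=BASELINE_ADJUSTMENT,
                          time_varying=TIME_VARYING_ADJUSTMENT,
                          truncation_percentile: float = 99.0) -> WeightSet:
    """Inverse-probability-of-adherence weights (censoring = deviation)."""
    return _fit_censor_weights(pm, "censor_deviation", "adherence",
                               baseline_covariates, time_varying,
                               truncation_percentile)


def fit_ltfu_weights(pm: pd.DataFrame,
                     baseline_covariates=BASELINE_ADJUSTMENT,
                     time_varying=TIME_VARYING_ADJUSTMENT,
                     truncation_percentile: float = 99.0) -> WeightSet:
    """Inverse-probability-of-remaining-enrolled weights (censoring = LTFU)."""
    return _fit_censor_weights(pm, "censor_ltfu", "ltfu",
                               baseline_covariates, time_varying,
                               truncation_percentile)


def combine_weights(*weight_sets: WeightSet) -> pd.Series:
    """Elementwise product of the truncated weight columns."""
    out = None
    for ws in weight_sets:
        out = ws.truncated if out is None else out * ws.truncated
    return out
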