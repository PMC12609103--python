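"""Observational analogs of the intention-to-treat and per-protocol effects.

ITT: weighted Cox proportional-hazards model (Efron ties, robust sandwich
variance) of time from time zero to death, with subjects never artificially
censored for protocol deviation.  Per-protocol: weighted pooled logistic
model of the monthly probability of death on person-months censored at
deviation, adjusted for the baseline set plus month and month²; with rare
monthly events the exponentiated strategy coefficient (an odds ratio) is the
hazard-ratio analog.  The logistic fits run on the in-package Newton solver
(person-month tables reach hundreds of thousands of rows) and their
variance is a sandwich clustered on patient, computed directly because the
model carries per-row IPW.

Cancer-specific mortality uses the cause-specific hazard convention: deaths
from other causes censor at the death month.

Confidence intervals are 95%, normal quantiles (z = 1.959964) on the
log-hazard-ratio scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from ._glm import fit_logistic
from .errors import DataError, EstimationError
from .weights import BASELINE_ADJUSTMENT, BASELINE_ADJUSTMENT_COHORT, design_matrix

Z95 = 1.959964


@dataclasses.dataclass
class EffectEstimate:
    analysis: str          # itt | per_protocol | per_protocol_ltfu | per_protocol_gap60
    outcome: str           # allcause | pca_specific
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    log_hr: float
    se_log_hr: float
    n_subjects: int
    n_events: int
    n_deviators: int
    model_kind: str        # cox | pooled_logistic
    se_kind: str = "robust"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def subject_table(cohort: pd.DataFrame, timelines: pd.DataFrame,
                  dataset) -> pd.DataFrame:
    """One row per subject: follow-up time (days) and event indicators.

    Exit is min(death, loss to follow-up, follow-up limit); deviation never
    censors here (intention-to-treat follow-up).
    """
    tl = cohort[["patient_id"]].merge(timelines, on="patient_id", how="left")
    tz = cohort["time_zero_day"].to_numpy(dtype=np.int64)
    fu_end = cohort["max_followup_end_day"].to_numpy(dtype=np.int64)
    wend = tl["window_end_day"].to_numpy(dtype=np.int64)  # min(death, ltfu, fu_end)
    death_day = tl["death_day"].to_numpy(dtype=np.int64)
    exit_day = np.minimum(wend, fu_end)
    died = death_day <= exit_day
    cause = cohort["patient_id"].map(
        dataset.deaths.set_index("patient_id")["cause"]).fillna("").to_numpy(dtype=object)
    out = cohort.copy()
    out["duration"] = (exit_day - tz + 1).astype(float)
    # delayed entry: eligibility requires survival through diagnosis + 183
    # days, so subjects join the risk set only once that day has passed
    dxd = cohort["diagnosis_day"].to_numpy(dtype=np.int64)
    out["entry"] = np.clip(dxd + 183 - tz, 0, None).astype(float)
    out["event_allcause"] = died
    out["event_pca"] = died & (cause == "pca")
    return out


def estimate_itt(subjects: pd.DataFrame, weights: pd.Series | None,
                 outcome: str = "allcause",
                 covariates=BASELINE_ADJUSTMENT_COHORT) -> EffectEstimate:
    """Weighted, covariate-adjusted Cox model of initiation vs none."""
    event_col = "event_allcause" if outcome == "allcause" else "event_pca"
    df = design_matrix(subjects, covariates).drop(columns="const")
    df["initiator"] = subjects["initiator"].astype(float).to_numpy()
    df["duration"] = subjects["duration"].to_numpy()
    df["entry"] = subjects["entry"].to_numpy() if "entry" in subjects else 0.0
    df["event"] = subjects[event_col].astype(bool).to_numpy()
    ev = subjects.groupby("initiator")[event_col].sum()
    if (ev == 0).any() or len(ev) < 2:
        raise EstimationError(
            f"ITT ({outcome}): zero events in a strategy stratum",
            diagnostics={"events_by_strategy": ev.to_dict()})
    df["_w"] = 1.0 if weights is None else np.asarray(weights, dtype=float)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="duration", event_col="event", weights_col="_w",
                entry_col="entry", robust=True)
    except Exception as exc:
        raise EstimationError(f"ITT ({outcome}): Cox fit failed: {exc}") from exc
    b = float(cph.params_["initiator"])
    se = float(cph.standard_errors_["initiator"])
    return EffectEstimate(
        analysis="itt", outcome=outcome,
        hazard_ratio=float(np.exp(b)),
        ci_lower=float(np.exp(b - Z95 * se)), ci_upper=float(np.exp(b + Z95 * se)),
        log_hr=b, se_log_hr=se,
        n_subjects=int(len(subjects)), n_events=int(subjects[event_col].sum()),
        n_deviators=0, model_kind="cox")


def _cluster_sandwich(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                      p: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Cluster-robust covariance for a weighted logistic score."""
    Wd = w * p * (1 - p)
    A = X.T @ (X * Wd[:, None])
    U = X * (w * (y - p))[:, None]
    Ug = pd.DataFrame(U).groupby(groups).sum().to_numpy()
    B = Ug.T @ Ug
    Ainv = np.linalg.pinv(A)
    return Ainv @ B @ Ainv


def pooled_logistic(pm: pd.DataFrame, weights: pd.Series | None,
                    outcome_col: str, covariates=BASELINE_ADJUSTMENT,
                    month_terms: bool = True) -> dict:
    """Weighted pooled logistic fit with patient-clustered robust SEs.

    Returns coefficient/SE for the strategy term plus fit metadata.  Rows
    censored by deviation or LTFU during the month are excluded (the event
    could not be observed there); administrative-censor rows contribute a
    full event-free month.
    """
    # deviation censoring takes effect at the END of the detection month:
    # the deviation row itself stays in the risk set (event-free if the
    # patient survived it), so the month contributes survivor time and
    # deaths symmetrically.  LTFU months are dropped (enrollment ended
    # mid-month).
    keep = ~pm["censor_ltfu"]
    if "immortal" in pm:
        # months overlapping the guaranteed-survival window (delayed entry)
        # or cut short by the administrative boundary are incomplete risk
        # months; they stay in the weight models but not in the hazard fit
        keep &= ~(pm["immortal"] | pm["partial_month"])
    sub = pm.loc[keep]
    y = sub[outcome_col].to_numpy(dtype=float)
    if y.sum() == 0:
        raise EstimationError(f"pooled logistic ({outcome_col}): zero events",
                              diagnostics={"n_rows": int(len(sub))})
    X = design_matrix(sub, covariates)
    X["initiator"] = sub["initiator"].astype(float).to_numpy()
    if month_terms:
        X["month"] = sub["month"].astype(float).to_numpy()
        X["month_sq"] = sub["month_sq"].astype(float).to_numpy()
    w = np.ones(len(sub)) if weights is None else \
        np.asarray(weights.loc[sub.index], dtype=float)
    res = fit_logistic(y, X, sample_weight=w,
                       context=f"pooled logistic ({outcome_col})")
    p = res.predict(X)
    cov = _cluster_sandwich(X.to_numpy(dtype=float), y, w, p,
                            sub["patient_id"].to_numpy())
    j = list(X.columns).index("initiator")
    return {
        "coef": float(res.params["initiator"]),
        "se": float(np.sqrt(cov[j, j])),
        "params": res.params.to_dict(),
        "n_rows": int(len(sub)),
        "n_events": int(y.sum()),
        "fitted": res,
    }


def estimate_per_protocol(pm: pd.DataFrame, weights: pd.Series | None,
                          outcome: str = "allcause",
                          covariates=BASELINE_ADJUSTMENT,
                          analysis: str = "per_protocol") -> EffectEstimate:
    """Weighted pooled-logistic per-protocol hazard-ratio analog."""
    outcome_col = "event_allcause" if outcome == "allcause" else "event_pca"
    work = pm if outcome == "allcause" else pca_specific_outcome(pm)
    fit = pooled_logistic(work, weights, outcome_col, covariates)
    b, se = fit["coef"], fit["se"]
    n_dev = int(pm["censor_deviation"].sum())
    return EffectEstimate(
        analysis=analysis, outcome=outcome,
        hazard_ratio=float(np.exp(b)),
        ci_lower=float(np.exp(b - Z95 * se)), ci_upper=float(np.exp(b + Z95 * se)),
        log_hr=b, se_log_hr=se,
        n_subjects=int(pm["patient_id"].nunique()), n_events=fit["n_events"],
        n_deviators=n_dev, model_kind="pooled_logistic")


def pca_specific_outcome(pm: pd.DataFrame) -> pd.DataFrame:
    """Recode person-months to the cancer-specific hazard convention.

    The event is cancer death; other-cause death censors at the death month
    (the row stays in the risk set with no event).
    """
    if not len(pm):
        return pm.copy()
    dead = pm["event_allcause"].to_numpy(dtype=bool)
    pca = pm["event_pca"].to_numpy(dtype=bool)
    if (pca & ~dead).any():
        raise DataError("person-months: cancer death without all-cause death flag")
    out = pm.copy()
    out["event_allcause"] = pca  # competing deaths leave the risk set silently
    return out


def run_sensitivity(dataset, cohort: pd.DataFrame, base_pm: pd.DataFrame,
                    treatment_weight_by_pid: pd.Series | None,
                    outcomes=("allcause", "pca_specific"),
                    truncation_percentile: float = 99.0) -> list[EffectEstimate]:
    """Per-protocol sensitivity suite: (a) add LTFU weights, (b) 60-day gap.

    ``treatment_weight_by_pid`` is the truncated stabilized baseline
    treatment weight indexed by patient_id; it is broadcast onto whichever
    person-month table each variant uses.
    """
    from .exposure import build_timelines
    from .persontime import expand_person_months
    from .weights import combine_weights, fit_adherence_weights, fit_ltfu_weights

    def _broadcast(pm):
        if treatment_weight_by_pid is None:
            return pd.Series(1.0, index=pm.index)
        return pd.Series(pm["patient_id"].map(treatment_weight_by_pid).to_numpy(),
                         index=pm.index)

    out: list[EffectEstimate] = []
    # (a) adherence × LTFU weights on the base (30-day gap) person-months
    adh = fit_adherence_weights(base_pm, truncation_percentile=truncation_percentile)
    ltf = fit_ltfu_weights(base_pm, truncation_percentile=truncation_percentile)
    w_ltfu = combine_weights(adh, ltf) * _broadcast(base_pm)
    for oc in outcomes:
        out.append(estimate_per_protocol(base_pm, w_ltfu, oc,
                                         analysis="per_protocol_ltfu"))
    # (b) re-derive exposure with the 60-day gap
    tl60 = build_timelines(dataset, cohort, gap_days=60)
    pm60 = expand_person_months(cohort, dataset, tl60)
    adh60 = fit_adherence_weights(pm60, truncation_percentile=truncation_percentile)
    w60 = adh60.truncated * _broadcast(pm60)
    for oc in outcomes:
        out.append(estimate_per_protocol(pm60, w60, oc,
                                         analysis="per_protocol_gap60"))
    return out
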