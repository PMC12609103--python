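"""Person-month expansion for discrete-time hazard modelling.

Each cohort patient contributes consecutive 30-day months from time zero
(month 0) until the first terminating cause.  Candidate terminations, with
the within-month priority death > deviation > loss-to-follow-up >
administrative end:

* death (event_allcause; event_pca when the recorded cause is cancer),
* protocol deviation (censor_deviation) from the exposure timelines,
* loss to follow-up (censor_ltfu) when Part D coverage ends before the
  follow-up limit,
* administrative end (censor_admin) at min(diagnosis + 1095 days,
  administrative end of study) — the month grid is anchored at time zero
  but truncated by the diagnosis-anchored 3-year date.

Time-varying covariates for month m reflect events dated strictly before
the start of month m (baseline conditions, measured in the year before
diagnosis, are present from month 0).  Covariates update only at month
boundaries.

The resulting table is the single interchange format between the weighting
and estimation stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import FOLLOWUP_CONTRAINDICATIONS
from .datamodel import ClaimsDataset, to_day
from .errors import ConfigurationError

BIG = 10**9

TIME_VARYING = ("diabetes", "chf", "cerebrovascular", "hypertension",
                "depression", "contraindication_any")

#: Baseline columns copied from the cohort onto every person-month row.
BASELINE_COLS = ("age", "race_ethnicity", "marital_status", "education_quartile",
                 "charlson", "pcp_visits", "diabetes", "chf", "cerebrovascular",
                 "hypertension", "depression")


def expand_person_months(cohort: pd.DataFrame, dataset: ClaimsDataset,
                         timelines: pd.DataFrame, horizon: int = 37) -> pd.DataFrame:
    """Expand the cohort into person-month rows.

    ``timelines`` must come from :func:`ttemu.exposure.build_timelines` with
    the active gap rule.  ``horizon`` is the maximum month index + 1; it must
    accommodate every patient's follow-up window.
    """
    if not len(cohort):
        return _empty()
    tl = cohort[["patient_id"]].merge(timelines, on="patient_id", how="left")
    tz = cohort["time_zero_day"].to_numpy(dtype=np.int64)
    fu_end = cohort["max_followup_end_day"].to_numpy(dtype=np.int64)
    admin_m = (fu_end - tz) // 30
    if int(admin_m.max()) >= horizon:
        raise ConfigurationError(
            f"horizon: {horizon} months cannot hold follow-up to month {int(admin_m.max())}")

    death_day = tl["death_day"].to_numpy(dtype=np.int64)
    death_ok = death_day <= fu_end
    death_m = np.where(death_ok, (death_day - tz) // 30, BIG)

    dev_m = tl["deviation_month"].to_numpy(dtype=np.int64)

    # loss to follow-up: Part D coverage ends before the follow-up limit
    d_cov = dataset.coverage[dataset.coverage["part"] == "D"]
    d_end = cohort["patient_id"].map(
        d_cov.assign(e=to_day(d_cov["end_date"])).groupby("patient_id")["e"].max()
    ).fillna(-1).to_numpy(dtype=np.int64)
    ltfu_m = np.where((d_end < fu_end) & (d_end < death_day),
                      np.maximum((d_end - tz), 0) // 30, BIG)

    # first terminating cause; ties by priority order
    cand = np.stack([death_m, dev_m, ltfu_m, admin_m])
    key = np.minimum(cand, BIG) * 10 + np.arange(4)[:, None]
    reason_idx = key.argmin(axis=0)
    exit_m = cand[reason_idx, np.arange(len(cohort))].astype(np.int64)

    n_rows = exit_m + 1
    ridx = np.repeat(np.arange(len(cohort)), n_rows)
    month = np.concatenate([np.arange(k) for k in n_rows]) if len(ridx) else \
        np.array([], dtype=np.int64)
    last = np.concatenate([np.arange(k) == k - 1 for k in n_rows]) if len(ridx) else \
        np.array([], dtype=bool)

    pm = pd.DataFrame({
        "patient_id": cohort["patient_id"].to_numpy()[ridx],
        "month": month,
        "month_sq": month ** 2,
        "strategy": cohort["strategy"].to_numpy()[ridx],
        "initiator": cohort["initiator"].to_numpy()[ridx].astype(int),
        "adherent_so_far": True,
    })
    # eligibility guarantees survival through diagnosis + 183 days; months
    # with any day inside that window are not fully at risk (immortal
    # person-time), so the hazard model must not treat them as complete
    # risk months.  Likewise a final month cut short by the administrative
    # boundary is an incomplete Bernoulli trial.
    dxd = cohort["diagnosis_day"].to_numpy(dtype=np.int64)
    mstart_all = tz[ridx] + 30 * month
    pm["immortal"] = mstart_all <= (dxd[ridx] + 183)
    pm["partial_month"] = (mstart_all + 29) > fu_end[ridx]
    for col in BASELINE_COLS:
        pm[f"base_{col}" if col in TIME_VARYING else col] = cohort[col].to_numpy()[ridx]

    cause = _death_cause(cohort, dataset)
    is_death = last & (reason_idx[ridx] == 0)
    pm["event_allcause"] = is_death
    pm["event_pca"] = is_death & (cause[ridx] == "pca")
    pm["censor_deviation"] = last & (reason_idx[ridx] == 1)
    pm["censor_ltfu"] = last & (reason_idx[ridx] == 2)
    pm["censor_admin"] = last & (reason_idx[ridx] == 3)

    # time-varying covariates: first event day per code vs month start
    events = dataset.events.assign(day=to_day(dataset.events["event_date"]))
    mstart = tz[ridx] + 30 * month
    for name in TIME_VARYING:
        if name == "contraindication_any":
            sub = events[events["event_code"].isin(FOLLOWUP_CONTRAINDICATIONS)]
        else:
            sub = events[events["event_code"] == name]
        first = cohort["patient_id"].map(
            sub.groupby("patient_id")["day"].min()).fillna(BIG).to_numpy(dtype=np.int64)
        pm[name] = (first[ridx] < mstart).astype(int)

    return pm


def _death_cause(cohort: pd.DataFrame, dataset: ClaimsDataset) -> np.ndarray:
    deaths = dataset.deaths
    cause = cohort["patient_id"].map(
        deaths.set_index("patient_id")["cause"]).fillna("").to_numpy(dtype=object)
    return cause


def _empty() -> pd.DataFrame:
    cols = ["patient_id", "month", "month_sq", "strategy", "initiator",
            "adherent_so_far", *BASELINE_COLS, "event_allcause", "event_pca",
            "censor_deviation", "censor_ltfu", "censor_admin", *TIME_VARYING]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
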