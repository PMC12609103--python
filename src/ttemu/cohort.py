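"""Eligibility screening, strategy assignment, and the attrition flow.

The screening criteria (in their fixed attribution order):

1. dx_in_window                advanced-cancer diagnosis 2008–2019
2. age_ge_66                   age >= 66 years at diagnosis
3. adt_within_6mo              hormonal fill or orchiectomy within 183 days
4. no_prior_metformin_6mo      no metformin fill in the 183 days before
                               diagnosis, with continuous Part D over that
                               window
5. no_contraindication         no hepatic failure / severe renal disease /
                               metabolic acidosis diagnosis in the prior year
6. one_year_prior_AB_no_HMO    continuous Parts A and B over the prior 365
                               days, no HMO span overlapping it
7. alive_enrolled_D_6mo_post   alive beyond day dx+183 and Part D continuous
                               through it

Calendar arithmetic: "6 months" = 183 days, "1 year" = 365 days, "3 years" =
1095 days; intervals closed at both ends.  Continuous enrollment requires the
window endpoints to be covered and tolerates interior administrative gaps of
up to 31 days between spans.  Excluded patients are
attributed to the FIRST failed criterion in the order above, so attrition
counts sum to the population size.

Strategy: a patient is an initiator iff the first metformin fill falls within
[dx, dx+183] (day 183 inclusive); time zero is max(ADT date, first fill) for
initiators and the ADT date for non-initiators.  Baseline covariates are
measured over the 365 days before diagnosis.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

from .config import BASELINE_CONTRAINDICATIONS
from .datamodel import ClaimsDataset, to_day
from .errors import DataError
from .synthetic import FOLLOWUP_DAYS, HALF_YEAR_DAYS, YEAR_DAYS, _day

CRITERIA = (
    "dx_in_window", "age_ge_66", "adt_within_6mo", "no_prior_metformin_6mo",
    "no_contraindication", "one_year_prior_AB_no_HMO", "alive_enrolled_D_6mo_post",
)

ENROLLMENT_GAP_TOLERANCE = 31  # days

#: Comorbidity covariates measured at baseline (year before diagnosis).
BASELINE_CONDITIONS = ("diabetes", "chf", "cerebrovascular", "hypertension", "depression")

#: Toy Charlson set: distinct conditions, each weight 1, capped at 3 ("3+").
CHARLSON_CONDITIONS = ("diabetes", "chf", "cerebrovascular", "hepatic_failure",
                       "severe_renal", "metabolic_acidosis")


@dataclasses.dataclass
class EligibilityResult:
    patient_id: object
    criteria: dict[str, bool]

    @property
    def eligible(self) -> bool:
        return all(self.criteria.values())

    def __getattr__(self, name):
        crit = object.__getattribute__(self, "criteria")
        if name in crit:
            return crit[name]
        raise AttributeError(name)


def _first_per_patient(df: pd.DataFrame, day_col: str, pids: pd.Series) -> np.ndarray:
    """Earliest day per patient, aligned to ``pids``; BIG where absent."""
    big = np.int64(10**9)
    if not len(df):
        return np.full(len(pids), big)
    agg = df.groupby("patient_id")[day_col].min()
    return pids.map(agg).fillna(big).to_numpy(dtype=np.int64)


def _continuous(coverage: pd.DataFrame, part: str, pids: pd.Series,
                w0: np.ndarray, w1: np.ndarray,
                tolerance: int = ENROLLMENT_GAP_TOLERANCE) -> np.ndarray:
    """True where the part's spans cover [w0, w1] continuously.

    Both window endpoints must be covered; interior uncovered runs of up to
    ``tolerance`` days between consecutive spans are treated as
    administrative gaps and ignored.
    """
    n = len(pids)
    sub = coverage[coverage["part"] == part]
    if not len(sub):
        return np.zeros(n, dtype=bool)
    sub = sub.assign(s=to_day(sub["start_date"]), e=to_day(sub["end_date"]))
    sub = sub.sort_values(["patient_id", "s"], kind="stable")
    win = pd.DataFrame({"patient_id": pids.to_numpy(), "w0": w0, "w1": w1})
    m = sub.merge(win, on="patient_id")
    m = m[(m["e"] >= m["w0"]) & (m["s"] <= m["w1"])]
    if not len(m):
        return np.zeros(n, dtype=bool)
    first = ~m["patient_id"].duplicated()
    # rightmost covered day seen so far; shift crosses groups but first rows
    # are masked by the `first` branch below
    frontier = m.groupby("patient_id", sort=False)["e"].cummax().shift()
    gap = m["s"].to_numpy() - np.where(first, m["w0"].to_numpy(),
                                       frontier.fillna(0).to_numpy() + 1)
    per = pd.DataFrame({
        "patient_id": m["patient_id"].to_numpy(),
        # the window start itself must be covered; interior gaps get tolerance
        "bad": np.where(first, gap > 0, gap > tolerance),
        "e": m["e"].to_numpy(),
    })
    agg = per.groupby("patient_id").agg(any_bad=("bad", "any"), max_e=("e", "max"))
    agg = agg.join(win.set_index("patient_id")[["w1"]])
    ok = (~agg["any_bad"]) & (agg["max_e"] >= agg["w1"])
    return pids.map(ok).fillna(False).to_numpy(dtype=bool)


def eligibility_table(dataset: ClaimsDataset,
                      dx_window: tuple[dt.date, dt.date] | None = None,
                      contraindication_codes=BASELINE_CONTRAINDICATIONS) -> pd.DataFrame:
    """Per-criterion booleans for every patient (vectorized check_eligibility)."""
    pats = dataset.patients
    pids = pats["patient_id"]
    n = len(pats)
    dx = to_day(pats["diagnosis_date"])
    birth = to_day(pats["birth_date"])

    out = pd.DataFrame({"patient_id": pids.to_numpy()})

    if dx_window is None:
        dx_window = (dt.date(2008, 1, 1), dt.date(2019, 12, 31))
    out["dx_in_window"] = (dx >= _day(dx_window[0])) & (dx <= _day(dx_window[1]))

    age = (dx - birth) / 365.25
    out["age_ge_66"] = age >= 66.0

    fills = dataset.fills.assign(day=to_day(dataset.fills["fill_date"]))
    events = dataset.events.assign(day=to_day(dataset.events["event_date"]))

    adt_f = fills[fills["drug"] == "adt_hormonal"]
    orch = events[events["event_code"] == "orchiectomy"]
    adt_days = np.minimum(_first_adt(adt_f, pids, dx), _first_adt(orch, pids, dx))
    out["adt_within_6mo"] = adt_days < 10**9

    met = fills[fills["drug"] == "metformin"]
    met_prior = met.merge(pd.DataFrame({"patient_id": pids, "dx": dx}), on="patient_id")
    met_prior = met_prior[(met_prior["day"] >= met_prior["dx"] - HALF_YEAR_DAYS)
                          & (met_prior["day"] <= met_prior["dx"] - 1)]
    has_prior = pids.isin(met_prior["patient_id"]).to_numpy()
    d_pre = _continuous(dataset.coverage, "D", pids, dx - HALF_YEAR_DAYS, dx)
    out["no_prior_metformin_6mo"] = (~has_prior) & d_pre

    contra = events[events["event_code"].isin(contraindication_codes)]
    contra = contra.merge(pd.DataFrame({"patient_id": pids, "dx": dx}), on="patient_id")
    contra = contra[(contra["day"] >= contra["dx"] - YEAR_DAYS) & (contra["day"] <= contra["dx"])]
    out["no_contraindication"] = ~pids.isin(contra["patient_id"]).to_numpy()

    a_ok = _continuous(dataset.coverage, "A", pids, dx - YEAR_DAYS, dx)
    b_ok = _continuous(dataset.coverage, "B", pids, dx - YEAR_DAYS, dx)
    hmo = dataset.coverage[dataset.coverage["part"] == "HMO"]
    hmo_overlap = np.zeros(n, dtype=bool)
    if len(hmo):
        h = hmo.assign(s=to_day(hmo["start_date"]), e=to_day(hmo["end_date"]))
        h = h.merge(pd.DataFrame({"patient_id": pids, "dx": dx}), on="patient_id")
        h = h[(h["e"] >= h["dx"] - YEAR_DAYS) & (h["s"] <= h["dx"])]
        hmo_overlap = pids.isin(h["patient_id"]).to_numpy()
    out["one_year_prior_AB_no_HMO"] = a_ok & b_ok & ~hmo_overlap

    death_day = _first_per_patient(
        dataset.deaths.assign(day=to_day(dataset.deaths["death_date"])), "day", pids)
    alive = death_day > dx + HALF_YEAR_DAYS
    d_post = _continuous(dataset.coverage, "D", pids, dx, dx + HALF_YEAR_DAYS)
    out["alive_enrolled_D_6mo_post"] = alive & d_post

    out["eligible"] = out[list(CRITERIA)].all(axis=1)
    return out


def _first_adt(df: pd.DataFrame, pids: pd.Series, dx: np.ndarray) -> np.ndarray:
    big = np.int64(10**9)
    if not len(df):
        return np.full(len(pids), big)
    m = df.merge(pd.DataFrame({"patient_id": pids, "dx": dx}), on="patient_id")
    m = m[(m["day"] >= m["dx"]) & (m["day"] <= m["dx"] + HALF_YEAR_DAYS)]
    if not len(m):
        return np.full(len(pids), big)
    agg = m.groupby("patient_id")["day"].min()
    return pids.map(agg).fillna(big).to_numpy(dtype=np.int64)


def check_eligibility(patient_id, dataset: ClaimsDataset, **kw) -> EligibilityResult:
    """Evaluate every screening criterion for one patient."""
    dataset.require_patient(patient_id)
    tab = eligibility_table(dataset, **kw)
    row = tab[tab["patient_id"] == patient_id].iloc[0]
    return EligibilityResult(patient_id, {c: bool(row[c]) for c in CRITERIA})


def build_cohort(dataset: ClaimsDataset,
                 dx_window: tuple[dt.date, dt.date] | None = None,
                 admin_end: dt.date = dt.date(2020, 12, 31),
                 contraindication_codes=BASELINE_CONTRAINDICATIONS,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen the population; return (cohort table, attrition flow).

    The cohort table has one row per eligible patient: strategy, time zero,
    baseline covariates, and the maximum follow-up end date
    min(diagnosis + 1095 days, administrative end).  The attrition flow
    lists, per criterion in screening order, the count removed because that
    was the first criterion they failed.
    """
    elig = eligibility_table(dataset, dx_window=dx_window,
                             contraindication_codes=contraindication_codes)
    n = len(elig)

    fail = ~elig[list(CRITERIA)].to_numpy(dtype=bool)
    first_fail = np.where(fail.any(axis=1), fail.argmax(axis=1), len(CRITERIA))
    counts = [int((first_fail == i).sum()) for i in range(len(CRITERIA))]
    attrition = pd.DataFrame({
        "criterion": list(CRITERIA) + ["eligible"],
        "removed": counts + [0],
        "remaining": list(n - np.cumsum(counts)) + [int(elig["eligible"].sum())],
    })

    keep = elig["eligible"].to_numpy(dtype=bool)
    pats = dataset.patients.loc[keep].reset_index(drop=True)
    if not len(pats):
        return _empty_cohort(), attrition

    pids = pats["patient_id"]
    dx = to_day(pats["diagnosis_date"])
    birth = to_day(pats["birth_date"])

    fills = dataset.fills.assign(day=to_day(dataset.fills["fill_date"]))
    events = dataset.events.assign(day=to_day(dataset.events["event_date"]))

    met = fills[fills["drug"] == "metformin"]
    m = met.merge(pd.DataFrame({"patient_id": pids, "dx": dx}), on="patient_id")
    m = m[(m["day"] >= m["dx"]) & (m["day"] <= m["dx"] + HALF_YEAR_DAYS)]
    first_fill = pids.map(m.groupby("patient_id")["day"].min()).to_numpy()
    initiator = ~np.isnan(first_fill)

    adt_f = fills[fills["drug"] == "adt_hormonal"]
    orch = events[events["event_code"] == "orchiectomy"]
    adt_day = np.minimum(_first_adt(adt_f, pids, dx), _first_adt(orch, pids, dx))

    time_zero = np.where(initiator,
                         np.maximum(adt_day, np.nan_to_num(first_fill, nan=0)),
                         adt_day).astype(np.int64)

    # baseline covariates: conditions and PCP visits in the prior 365 days
    base = events.merge(pd.DataFrame({"patient_id": pids, "dx": dx}), on="patient_id")
    base = base[(base["day"] >= base["dx"] - YEAR_DAYS) & (base["day"] <= base["dx"])]
    cohort = pd.DataFrame({
        "patient_id": pids.to_numpy(),
        "strategy": np.where(initiator, "initiator", "non_initiator"),
        "initiator": initiator,
        "time_zero_day": time_zero,
        "diagnosis_day": dx,
        "age": (dx - birth) / 365.25,
        "race_ethnicity": pats["race_ethnicity"].to_numpy(),
        "marital_status": pats["marital_status"].to_numpy(),
        "education_quartile": pats["education_quartile"].to_numpy(),
        "max_followup_end_day": np.minimum(dx + FOLLOWUP_DAYS, _day(admin_end)),
    })
    for cond in BASELINE_CONDITIONS:
        sub = base[base["event_code"] == cond]
        cohort[cond] = pids.isin(sub["patient_id"]).to_numpy().astype(int)
    charl = base[base["event_code"].isin(CHARLSON_CONDITIONS)]
    cc = charl.groupby("patient_id")["event_code"].nunique()
    cohort["charlson"] = np.minimum(pids.map(cc).fillna(0).to_numpy(dtype=np.int64), 3)
    pcp = base[base["event_code"] == "pcp_visit"].groupby("patient_id").size()
    cohort["pcp_visits"] = pids.map(pcp).fillna(0).to_numpy(dtype=np.int64)

    if (cohort["time_zero_day"] < cohort["diagnosis_day"]).any():
        raise DataError("cohort: time zero before diagnosis")
    return cohort, attrition


def _empty_cohort() -> pd.DataFrame:
    cols = ["patient_id", "strategy", "initiator", "time_zero_day", "diagnosis_day",
            "age", "race_ethnicity", "marital_status", "education_quartile",
            "max_followup_end_day", *BASELINE_CONDITIONS, "charlson", "pcp_visits"]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def assign_strategy(patient_id, dataset: ClaimsDataset, **kw) -> pd.Series:
    """CohortRecord for one eligible patient (contract: must be eligible)."""
    res = check_eligibility(patient_id, dataset,
                            **{k: v for k, v in kw.items() if k != "admin_end"})
    if not res.eligible:
        raise DataError(f"assign_strategy called on ineligible patient {patient_id!r}")
    cohort, _ = build_cohort(dataset, **kw)
    return cohort[cohort["patient_id"] == patient_id].iloc[0]
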