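"""Prescription-gap exposure engine.

Converts fill sequences into day-level on-drug status and locates
discontinuation under a configurable gap window (30 days primary, 60 days
sensitivity): a day is covered iff it lies within [fill_date,
fill_date + days_supply − 1] of some fill — no stockpiling, overlapping
supply does not extend coverage beyond the union of fill intervals — and
discontinuation occurs at the first uncovered run inside the observation
window longer than ``gap_days``, dated to run_start + gap_days (i.e. the
day the allowed gap is exhausted; equivalently supply-end + gap_days + 1).
An initiator with no fills at all "discontinues" at time_zero + gap_days.
Death or follow-up end before a gap completes means no discontinuation:
one cannot deviate after exit.

Protocol deviations:

* initiators deviate at the first discontinuation not preceded by a
  contraindication diagnosis (hepatic failure, severe renal disease,
  metabolic acidosis, or new-onset CHF) on or before the discontinuation
  date;
* non-initiators deviate at their first metformin fill after the 6-month
  classification window unless a diabetes diagnosis (the indication)
  precedes the fill.

Deviation months are 0-based 30-day bins from time zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import FOLLOWUP_CONTRAINDICATIONS
from .datamodel import ClaimsDataset, to_day
from .errors import DataError
from .synthetic import HALF_YEAR_DAYS

BIG = 10**9


@dataclasses.dataclass
class ExposureTimeline:
    patient_id: object
    time_zero_day: int
    window_end_day: int
    discontinuation_day: int | None
    deviation_month: int | None
    deviation_reason: str  # discontinued_no_contraindication | initiated_no_indication | none


def coverage_days(fill_days, days_supply, window: tuple[int, int]) -> np.ndarray:
    """Day-indexed on-drug indicator over [window[0], window[1]].

    ``fill_days`` and ``days_supply`` are parallel sequences (scalar supply
    broadcast).  Coverage is the union of the fill intervals.
    """
    w0, w1 = int(window[0]), int(window[1])
    fill_days = np.asarray(fill_days, dtype=np.int64)
    supply = np.broadcast_to(np.asarray(days_supply, dtype=np.int64), fill_days.shape)
    if len(fill_days) and (supply < 1).any():
        raise DataError("fills: days_supply below 1")
    out = np.zeros(w1 - w0 + 1, dtype=bool)
    for f, s in zip(fill_days, supply):
        lo, hi = max(f, w0), min(f + s - 1, w1)
        if lo <= hi:
            out[lo - w0: hi - w0 + 1] = True
    return out


def detect_discontinuation(fill_days, days_supply, gap_days: int,
                           window: tuple[int, int]) -> int | None:
    """First discontinuation day under the gap rule, or None.

    Scans the union coverage for the first uncovered run of more than
    ``gap_days`` days starting within the window; returns run_start +
    gap_days.  A run cut short by the window end does not trigger.
    """
    w0, w1 = int(window[0]), int(window[1])
    fill_days = np.asarray(fill_days, dtype=np.int64)
    supply = np.broadcast_to(np.asarray(days_supply, dtype=np.int64), fill_days.shape)
    if len(fill_days) and (supply < 1).any():
        raise DataError("fills: days_supply below 1")
    order = np.argsort(fill_days, kind="stable")
    frontier = w0 - 1  # last covered day seen so far
    for k in order:
        f, e = int(fill_days[k]), int(fill_days[k] + supply[k] - 1)
        if f > frontier + 1:
            run_start = frontier + 1
            if f - run_start > gap_days and run_start + gap_days <= w1:
                return run_start + gap_days
        frontier = max(frontier, e)
    run_start = frontier + 1
    if run_start + gap_days <= w1:
        return run_start + gap_days
    return None


def discontinuation_table(fills: pd.DataFrame, cohort: pd.DataFrame,
                          window_end: np.ndarray, gap_days: int) -> np.ndarray:
    """Vectorized ``detect_discontinuation`` for every cohort patient.

    ``window_end`` is the per-patient exposure window end (death or
    follow-up end, whichever first).  Returns discontinuation day per
    cohort row, BIG where none.
    """
    pids = cohort["patient_id"]
    tz = cohort["time_zero_day"].to_numpy(dtype=np.int64)
    met = fills[fills["drug"] == "metformin"]
    met = met.assign(day=to_day(met["fill_date"]))
    if (met["days_supply"] < 1).any():
        raise DataError("fills: days_supply below 1")
    win = pd.DataFrame({"patient_id": pids.to_numpy(), "tz": tz, "wend": window_end})
    m = met.merge(win, on="patient_id")
    m = m[m["day"] <= m["wend"]]
    m = m.sort_values(["patient_id", "day"], kind="stable")
    m["end"] = m["day"] + m["days_supply"] - 1
    frontier = m.groupby("patient_id", sort=False)["end"].cummax().shift()
    first = (~m["patient_id"].duplicated()).to_numpy()
    prev_end = np.where(first, m["tz"].to_numpy() - 1, frontier.fillna(0).to_numpy())
    run_start = prev_end + 1
    gap_break = (m["day"].to_numpy() - run_start > gap_days) \
        & (run_start + gap_days <= m["wend"].to_numpy()) \
        & (run_start + gap_days >= m["tz"].to_numpy())
    cand = pd.Series(np.where(gap_break, run_start + gap_days, BIG),
                     index=m.index).groupby(m["patient_id"]).min()
    # tail run after the last fill
    tail = m.groupby("patient_id").agg(last_end=("end", "max"), wend=("wend", "max"),
                                       tz=("tz", "max"))
    tail_day = np.maximum(tail["last_end"] + 1, tail["tz"]) + gap_days
    tail_cand = pd.Series(np.where(tail_day <= tail["wend"], tail_day, BIG),
                          index=tail.index)
    per_patient = pd.concat([cand, tail_cand], axis=1).min(axis=1)
    out = pids.map(per_patient).to_numpy()
    # initiators with no metformin fills at all: discontinue at tz + gap_days
    missing = np.isnan(out)
    out = np.where(missing, tz + gap_days, out)
    no_fill_ok = (tz + gap_days) <= window_end
    out = np.where(missing & ~no_fill_ok, BIG, out)
    return out.astype(np.int64)


def build_timelines(dataset: ClaimsDataset, cohort: pd.DataFrame,
                    gap_days: int = 30) -> pd.DataFrame:
    """Per-patient exposure/deviation summary under the given gap rule.

    Columns: patient_id, window_end_day (min of death and follow-up end),
    discontinuation_day (BIG = none), deviation_day, deviation_month (BIG =
    none), deviation_reason.
    """
    pids = cohort["patient_id"]
    tz = cohort["time_zero_day"].to_numpy(dtype=np.int64)
    fu_end = cohort["max_followup_end_day"].to_numpy(dtype=np.int64)
    init = cohort["initiator"].to_numpy(dtype=bool)

    deaths = dataset.deaths.assign(day=to_day(dataset.deaths["death_date"]))
    death_day = pids.map(deaths.groupby("patient_id")["day"].min()).fillna(BIG) \
        .to_numpy(dtype=np.int64)
    # observable follow-up ends at death, disenrollment (end of Part D
    # drug coverage), or the follow-up limit — fills beyond it are unseen
    d_cov = dataset.coverage[dataset.coverage["part"] == "D"]
    d_end = pids.map(
        d_cov.assign(e=to_day(d_cov["end_date"])).groupby("patient_id")["e"].max()
    ).fillna(-1).to_numpy(dtype=np.int64)
    wend = np.minimum.reduce([fu_end, death_day, d_end])

    disc = discontinuation_table(dataset.fills, cohort, wend, gap_days)
    disc[~init] = BIG

    events = dataset.events.assign(day=to_day(dataset.events["event_date"]))
    contra = events[events["event_code"].isin(FOLLOWUP_CONTRAINDICATIONS)]
    # prevalent CHF is a baseline covariate, not an exemption: only events
    # after time zero count as "development of a contraindication"
    contra_post = contra.merge(
        pd.DataFrame({"patient_id": pids.to_numpy(), "tz": tz}), on="patient_id")
    contra_post = contra_post[contra_post["day"] > contra_post["tz"]]
    first_contra = pids.map(contra_post.groupby("patient_id")["day"].min()) \
        .fillna(BIG).to_numpy(dtype=np.int64)

    dev_day = np.full(len(cohort), BIG, dtype=np.int64)
    reason = np.full(len(cohort), "none", dtype=object)
    init_dev = init & (disc < BIG) & (first_contra > disc)
    dev_day[init_dev] = disc[init_dev]
    reason[init_dev] = "discontinued_no_contraindication"

    # non-initiators: first metformin fill after the classification window
    met = dataset.fills[dataset.fills["drug"] == "metformin"]
    met = met.assign(day=to_day(met["fill_date"]))
    dxd = cohort["diagnosis_day"].to_numpy(dtype=np.int64)
    mm = met.merge(pd.DataFrame({"patient_id": pids.to_numpy(),
                                 "cut": dxd + HALF_YEAR_DAYS, "wend": wend}),
                   on="patient_id")
    mm = mm[(mm["day"] > mm["cut"]) & (mm["day"] <= mm["wend"])]
    first_offprot = pids.map(mm.groupby("patient_id")["day"].min()).fillna(BIG) \
        .to_numpy(dtype=np.int64)
    dia = events[events["event_code"] == "diabetes"]
    first_dia = pids.map(dia.groupby("patient_id")["day"].min()).fillna(BIG) \
        .to_numpy(dtype=np.int64)
    ni_dev = ~init & (first_offprot < BIG) & (first_dia > first_offprot)
    dev_day[ni_dev] = first_offprot[ni_dev]
    reason[ni_dev] = "initiated_no_indication"

    dev_month = np.where(dev_day < BIG, (dev_day - tz) // 30, BIG)
    return pd.DataFrame({
        "patient_id": pids.to_numpy(), "time_zero_day": tz, "window_end_day": wend,
        "death_day": death_day,
        "discontinuation_day": disc, "deviation_day": dev_day,
        "deviation_month": dev_month, "deviation_reason": reason,
    })


def find_deviation(record, timeline_row) -> tuple[int | None, str]:
    """(deviation_month, reason) for one patient from a timelines row."""
    month = timeline_row["deviation_month"]
    if month >= BIG:
        return None, "none"
    return int(month), str(timeline_row["deviation_reason"])
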