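"""Shared fixtures: a small default dataset and a hand-built micro dataset."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ttemu.config import SimulationConfig
from ttemu.datamodel import ClaimsDataset
from ttemu.synthetic import generate_population

EPOCH = dt.date(1970, 1, 1)


def day(iso: str) -> int:
    return (dt.date.fromisoformat(iso) - EPOCH).days


def ts(days):
    return pd.to_datetime(np.asarray(days, dtype="int64"), unit="D")


@pytest.fixture(scope="session")
def default_dataset() -> ClaimsDataset:
    return generate_population(SimulationConfig(n_patients=2000, seed=7))


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(n_patients=2000, seed=7)


def micro_dataset(patients_rows, coverage_rows=None, fills_rows=None,
                  events_rows=None, deaths_rows=None) -> ClaimsDataset:
    """Build a tiny ClaimsDataset from row tuples.

    patients_rows: (pid, birth, dx) ISO dates; demographics get defaults.
    coverage_rows: (pid, part, start, end); default: A/B/D from dx-500 to
    2020-12-31 for every patient.
    fills_rows: (pid, drug, date, supply).
    events_rows: (pid, code, date).
    deaths_rows: (pid, date, cause).
    """
    pats = pd.DataFrame(
        [{"patient_id": p, "birth_date": ts([day(b)])[0], "diagnosis_date": ts([day(d)])[0],
          "race_ethnicity": "nh_white", "marital_status": "married",
          "education_quartile": 2, "poverty_quartile": 2, "rurality": "metro"}
         for p, b, d in patients_rows])
    if coverage_rows is None:
        coverage_rows = []
        for p, _, d in patients_rows:
            for part in ("A", "B", "D"):
                coverage_rows.append((p, part,
                                      (dt.date.fromisoformat(d) - dt.timedelta(days=500)).isoformat(),
                                      "2020-12-31"))
    cov = pd.DataFrame(
        [{"patient_id": p, "part": part, "start_date": ts([day(s)])[0],
          "end_date": ts([day(e)])[0]} for p, part, s, e in coverage_rows])
    fills = pd.DataFrame(
        [{"patient_id": p, "drug": drug, "fill_date": ts([day(d)])[0],
          "days_supply": s} for p, drug, d, s in (fills_rows or [])],
        columns=["patient_id", "drug", "fill_date", "days_supply"])
    if not len(fills):
        fills = fills.astype({"patient_id": "int64", "days_supply": "int64"})
        fills["fill_date"] = pd.to_datetime(fills["fill_date"])
    events = pd.DataFrame(
        [{"patient_id": p, "event_code": c, "event_date": ts([day(d)])[0]}
         for p, c, d in (events_rows or [])],
        columns=["patient_id", "event_code", "event_date"])
    if not len(events):
        events = events.astype({"patient_id": "int64"})
        events["event_date"] = pd.to_datetime(events["event_date"])
    deaths = pd.DataFrame(
        [{"patient_id": p, "death_date": ts([day(d)])[0], "cause": c}
         for p, d, c in (deaths_rows or [])],
        columns=["patient_id", "death_date", "cause"])
    if not len(deaths):
        deaths = deaths.astype({"patient_id": "int64"})
        deaths["death_date"] = pd.to_datetime(deaths["death_date"])
    ds = ClaimsDataset(patients=pats, coverage=cov, fills=fills, events=events,
                       deaths=deaths)
    ds.validate()
    return ds
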