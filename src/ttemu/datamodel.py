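"""The claims-data container and its delimited-text serialization.

A :class:`ClaimsDataset` holds five tables sharing ``patient_id``:

patients   patient_id, birth_date, diagnosis_date, race_ethnicity,
           marital_status, education_quartile, poverty_quartile, rurality
coverage   patient_id, part ∈ {A, B, D, HMO}, start_date, end_date
fills      patient_id, drug ∈ {metformin, adt_hormonal}, fill_date, days_supply
events     patient_id, event_code, event_date
deaths     patient_id, death_date, cause ∈ {pca, other}

Dates are pandas datetime64 columns in memory and ISO-8601 strings on disk.
Each CSV starts with a versioned schema comment line so files are
self-describing; pandas reads them back with ``comment='#'``.

Synthetic datasets additionally carry a ``truth`` table — the generator's
per-patient ground-truth bookkeeping (planted violations, true deviation and
exit months).  ``truth`` is not part of the claims schema and is never used
by the analysis stages; it exists so tests can compare pipeline output
against the generative plan.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, PatientLookupError

SCHEMA_VERSION = "claims-v1"

EVENT_CODES = (
    "diabetes", "chf", "cerebrovascular", "hypertension", "depression",
    "hepatic_failure", "severe_renal", "metabolic_acidosis", "orchiectomy",
    "pcp_visit",
)

_TABLES = ("patients", "coverage", "fills", "events", "deaths")
_DATE_COLS = {
    "patients": ["birth_date", "diagnosis_date"],
    "coverage": ["start_date", "end_date"],
    "fills": ["fill_date"],
    "events": ["event_date"],
    "deaths": ["death_date"],
}


@dataclasses.dataclass
class ClaimsDataset:
    patients: pd.DataFrame
    coverage: pd.DataFrame
    fills: pd.DataFrame
    events: pd.DataFrame
    deaths: pd.DataFrame
    truth: pd.DataFrame | None = None

    def validate(self) -> None:
        """Raise DataError on the first violated schema invariant."""
        known = set(self.patients["patient_id"])
        for name in ("coverage", "fills", "events", "deaths"):
            tab = getattr(self, name)
            if len(tab) and not set(tab["patient_id"]).issubset(known):
                raise DataError(f"{name}: patient_id not present in patients table")
        if len(self.coverage) and (self.coverage["end_date"] < self.coverage["start_date"]).any():
            raise DataError("coverage: end_date before start_date")
        if len(self.fills) and (self.fills["days_supply"] < 1).any():
            raise DataError("fills: days_supply below 1")
        if len(self.deaths):
            merged = self.deaths.merge(
                self.patients[["patient_id", "diagnosis_date"]], on="patient_id")
            if (merged["death_date"] < merged["diagnosis_date"]).any():
                raise DataError("deaths: death_date before diagnosis_date")
            if not set(self.deaths["cause"]).issubset({"pca", "other"}):
                raise DataError("deaths: unknown cause label")

    def require_patient(self, patient_id) -> None:
        if patient_id not in set(self.patients["patient_id"]):
            raise PatientLookupError(f"unknown patient_id: {patient_id!r}")

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in _TABLES:
            tab = getattr(self, name).copy()
            for col in _DATE_COLS[name]:
                tab[col] = pd.to_datetime(tab[col]).dt.strftime("%Y-%m-%d")
            path = directory / f"{name}.csv"
            with open(path, "w") as fh:
                fh.write(f"# schema: {SCHEMA_VERSION}/{name}\n")
                tab.to_csv(fh, index=False)

    @classmethod
    def read(cls, directory: str | Path) -> "ClaimsDataset":
        directory = Path(directory)
        tables = {}
        for name in _TABLES:
            path = directory / f"{name}.csv"
            if not path.exists():
                raise DataError(f"missing claims table: {path}")
            tab = pd.read_csv(path, comment="#")
            for col in _DATE_COLS[name]:
                tab[col] = pd.to_datetime(tab[col])
            tables[name] = tab
        ds = cls(**tables)
        ds.validate()
        return ds


def to_day(dates) -> np.ndarray:
    """Convert datetime-like values to integer days since 1970-01-01."""
    return (pd.to_datetime(dates).astype("int64") // 86_400_000_000_000).to_numpy() \
        if isinstance(dates, (pd.Series, pd.Index)) else \
        np.asarray(pd.to_datetime(dates).value // 86_400_000_000_000)


def from_day(days) -> pd.Series | pd.Timestamp:
    """Inverse of :func:`to_day`."""
    if np.isscalar(days):
        return pd.Timestamp("1970-01-01") + pd.Timedelta(days=int(days))
    return pd.Series(pd.to_datetime(np.asarray(days, dtype="int64"), unit="D"))
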