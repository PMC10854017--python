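"""Domain types and CSV I/O for longitudinal emergency-department visit records.

A cohort is a collection of patient histories, each an ordered sequence of ED
visits.  Every visit carries the feature set used throughout the pipeline:
age at visit, CTAS triage level (1 = resuscitation ... 5 = non-urgent, 9 =
unknown), a disposition code, a most-responsible diagnosis code, and one or
more service-type codes identifying the responsible health professionals.

Storage format is a one-row-per-visit CSV (UTF-8, header required) with
columns ``patient_id, visit_date, age_years, triage_level, disposition_code,
diagnosis_code, service_codes``; multiple service codes are packed into one
pipe-delimited cell.  Two visits of the same patient on the same date are
kept as distinct visits in file order: dates alone define the temporal
order, and the sort used here is stable.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "VisitRecord",
    "PatientHistory",
    "Vocabularies",
    "Cohort",
    "CohortError",
    "SchemaError",
    "RowError",
    "EmptyCohortError",
    "DEFAULT_SCHEMA",
    "read_cohort",
    "write_cohort",
]

TRIAGE_LEVELS = frozenset({1, 2, 3, 4, 5, 9})
AGE_MIN, AGE_MAX = 4.0, 18.0

#: default column-name mapping for the visit-table CSV dialect
DEFAULT_SCHEMA: dict[str, str] = {
    "patient_id": "patient_id",
    "visit_date": "visit_date",
    "age_years": "age_years",
    "triage_level": "triage_level",
    "disposition_code": "disposition_code",
    "diagnosis_code": "diagnosis_code",
    "service_codes": "service_codes",
}

SERVICE_DELIMITER = "|"


class CohortError(ValueError):
    """Base class for cohort I/O and validation errors."""


class SchemaError(CohortError):
    """A required column is missing from the input file."""


class RowError(CohortError):
    """A row failed validation; carries the 1-based data row number."""

    def __init__(self, row_number: int, message: str):
        self.row_number = row_number
        super().__init__(f"row {row_number}: {message}")


class EmptyCohortError(CohortError):
    """The input file contains no visit rows."""


@dataclass(frozen=True)
class VisitRecord:
    """One ED visit and its features.

    ``service_codes`` is a non-empty frozenset: a visit may involve several
    responsible service types simultaneously.
    """

    patient_id: str
    visit_date: _dt.date
    age_years: float
    triage_level: int
    disposition_code: str
    diagnosis_code: str
    service_codes: frozenset[str]

    def __post_init__(self):
        if not (AGE_MIN <= self.age_years <= AGE_MAX):
            raise ValueError(
                f"age_years {self.age_years} outside [{AGE_MIN}, {AGE_MAX}]"
            )
        if self.triage_level not in TRIAGE_LEVELS:
            raise ValueError(
                f"triage_level {self.triage_level} not in {sorted(TRIAGE_LEVELS)}"
            )
        if not self.service_codes:
            raise ValueError("service_codes must be non-empty")
        if not isinstance(self.visit_date, _dt.date):
            raise ValueError("visit_date must be a datetime.date")


@dataclass(frozen=True)
class PatientHistory:
    """A patient's visits in chronological order (stable on date ties)."""

    patient_id: str
    visits: tuple[VisitRecord, ...]

    def __post_init__(self):
        if not self.visits:
            raise ValueError("PatientHistory requires at least one visit")
        dates = [v.visit_date for v in self.visits]
        if dates != sorted(dates):
            # normalize: stable sort keeps same-date visits in input order
            object.__setattr__(
                self,
                "visits",
                tuple(sorted(self.visits, key=lambda v: v.visit_date)),
            )

    @property
    def n(self) -> int:
        return len(self.visits)


@dataclass(frozen=True)
class Vocabularies:
    """The four categorical vocabularies present in a cohort, sorted."""

    triage: tuple[int, ...]
    disposition: tuple[str, ...]
    diagnosis: tuple[str, ...]
    service: tuple[str, ...]

    @classmethod
    def from_visits(cls, visits: Iterable[VisitRecord]) -> "Vocabularies":
        tri, disp, diag, svc = set(), set(), set(), set()
        for v in visits:
            tri.add(v.triage_level)
            disp.add(v.disposition_code)
            diag.add(v.diagnosis_code)
            svc.update(v.service_codes)
        return cls(
            triage=tuple(sorted(tri)),
            disposition=tuple(sorted(disp)),
            diagnosis=tuple(sorted(diag)),
            service=tuple(sorted(svc)),
        )


@dataclass
class Cohort:
    """A set of patient histories plus the vocabularies they span."""

    histories: list[PatientHistory]
    vocabularies: Vocabularies = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        ids = [h.patient_id for h in self.histories]
        if len(ids) != len(set(ids)):
            raise ValueError("patient_id must be unique across histories")
        if self.vocabularies is None:
            self.vocabularies = Vocabularies.from_visits(self.iter_visits())

    def iter_visits(self) -> Iterable[VisitRecord]:
        for h in self.histories:
            yield from h.visits

    def __len__(self) -> int:
        return len(self.histories)


def _parse_services(cell: str) -> frozenset[str]:
    codes = frozenset(c.strip() for c in str(cell).split(SERVICE_DELIMITER) if c.strip())
    return codes


def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
) -> Cohort:
    """Read the visit-table CSV at *path* into a :class:`Cohort`.

    Parameters
    ----------
    path
        CSV file with one row per visit.
    schema
        Mapping from canonical field names (the keys of
        :data:`DEFAULT_SCHEMA`) to the column names actually used in the
        file.  Omitted keys fall back to the defaults.

    Raises
    ------
    SchemaError
        if a required column is absent.
    RowError
        on an unparseable date or out-of-range age, naming the data row.
    EmptyCohortError
        if the file has no data rows.
    """
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for canonical, column in cols.items():
        if column not in df.columns:
            raise SchemaError(f"missing required column {column!r} (for {canonical})")
    if len(df) == 0:
        raise EmptyCohortError(f"no visit rows in {path}")

    visits_by_patient: dict[str, list[VisitRecord]] = {}
    order: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            date = _dt.date.fromisoformat(str(r[cols["visit_date"]]).strip())
        except ValueError as exc:
            raise RowError(i, f"unparseable visit_date: {exc}") from exc
        try:
            age = float(r[cols["age_years"]])
            triage = int(float(r[cols["triage_level"]]))
            visit = VisitRecord(
                patient_id=str(r[cols["patient_id"]]),
                visit_date=date,
                age_years=age,
                triage_level=triage,
                disposition_code=str(r[cols["disposition_code"]]),
                diagnosis_code=str(r[cols["diagnosis_code"]]),
                service_codes=_parse_services(r[cols["service_codes"]]),
            )
        except ValueError as exc:
            raise RowError(i, str(exc)) from exc
        if visit.patient_id not in visits_by_patient:
            order.append(visit.patient_id)
        visits_by_patient.setdefault(visit.patient_id, []).append(visit)

    histories = [
        PatientHistory(pid, tuple(sorted(visits_by_patient[pid], key=lambda v: v.visit_date)))
        for pid in order
    ]
    return Cohort(histories=histories)


def write_cohort(cohort: Cohort, path) -> None:
    """Write *cohort* in the visit-table CSV dialect.

    ``read_cohort(write_cohort(c))`` reproduces ``c`` up to field ordering;
    service sets are serialized sorted and pipe-delimited.
    """
    rows = []
    for h in cohort.histories:
        for v in h.visits:
            rows.append(
                {
                    "patient_id": v.patient_id,
                    "visit_date": v.visit_date.isoformat(),
                    "age_years": v.age_years,
                    "triage_level": v.triage_level,
                    "disposition_code": v.disposition_code,
                    "diagnosis_code": v.diagnosis_code,
                    "service_codes": SERVICE_DELIMITER.join(sorted(v.service_codes)),
                }
            )
    df = pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA))
    df.to_csv(path, index=False)
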