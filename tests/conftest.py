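import datetime as dt

import pytest

from edrevisit.ehr_data import PatientHistory, VisitRecord
from edrevisit.preprocessing import PreprocessConfig


@pytest.fixture
def pp_cfg():
    return PreprocessConfig()


@pytest.fixture
def make_visit():
    """Factory for VisitRecords with sensible defaults."""

    def _make(patient_id="P1", date="2020-01-01", age=12.0, triage=3,
              disposition="DISP00", diagnosis="DX0000", services=("SVC00",)):
        return VisitRecord(
            patient_id=patient_id,
            visit_date=dt.date.fromisoformat(date),
            age_years=age,
            triage_level=triage,
            disposition_code=disposition,
            diagnosis_code=diagnosis,
            service_codes=frozenset(services),
        )

    return _make


@pytest.fixture
def make_history(make_visit):
    """Factory for a single-patient history from a list of ISO dates."""

    def _make(dates, patient_id="P1", **visit_kwargs):
        visits = tuple(
            make_visit(patient_id=patient_id, date=d, **visit_kwargs) for d in dates
        )
        return PatientHistory(patient_id, visits)

    return _make
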