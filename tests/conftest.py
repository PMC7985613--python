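import pandas as pd
import pytest

from carecontacts import default_codelists


@pytest.fixture(scope="session")
def codelists():
    return default_codelists()


@pytest.fixture()
def patient_factory():
    """Build a single patient record Series with sensible defaults."""

    def make(
        pid="P1",
        birth="1979-07-01",
        sex="female",
        region="London",
        ethnicity="White",
        reg_start="2010-01-01",
        reg_end=None,
        death=None,
    ):
        return pd.Series(
            {
                "patient_id": pid,
                "birth_date": pd.Timestamp(birth),
                "sex": sex,
                "region": region,
                "ethnicity": ethnicity,
                "registration_start": pd.Timestamp(reg_start),
                "registration_end": pd.Timestamp(reg_end) if reg_end else pd.NaT,
                "death_date": pd.Timestamp(death) if death else pd.NaT,
            }
        )

    return make


@pytest.fixture()
def events_factory():
    """Build a clinical-events frame from (patient_id, date, code) tuples."""

    def make(rows):
        return pd.DataFrame(
            [
                {
                    "patient_id": pid,
                    "event_date": pd.Timestamp(date),
                    "code": code,
                    "source": "diagnosis",
                }
                for pid, date, code in rows
            ],
            columns=["patient_id", "event_date", "code", "source"],
        )

    return make
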