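import datetime as dt

import pytest

import autoval as av
from importlib import resources

WHEN = dt.datetime(2025, 6, 1, 9, 0)


@pytest.fixture(scope="session")
def example_config() -> av.EngineConfig:
    """The packaged chemistry-panel example configuration."""
    path = resources.files("autoval.data") / "example_config.yaml"
    return av.load_config(str(path))


@pytest.fixture()
def adult():
    return av.PatientInfo(
        patient_id="PT1",
        date_of_birth=dt.date(1980, 3, 15),
        sex=av.Sex.female,
    )


@pytest.fixture()
def make_record(adult):
    """Factory for result records; defaults pass every glucose rule."""

    def _make(value=5.5, test_code="GLU", patient=None, timestamp=WHEN,
              flags=(), hil=None, sample_id="S1", unit="mmol/L", analyzer=None):
        return av.ResultRecord(
            sample_id=sample_id,
            test_code=test_code,
            value=value,
            unit=unit,
            timestamp=timestamp,
            patient=patient or adult,
            analyzer=analyzer,
            flags=list(flags),
            hil=hil or av.HILIndices(hemolysis=0.0, icterus=0.0, lipemia=0.0),
        )

    return _make
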