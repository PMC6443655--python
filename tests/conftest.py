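import pytest
from hypothesis import settings

from comorec.claims import ClaimRecord, ClaimsDataset

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")


def make_record(
    patient_id="P1",
    age=30,
    sex="F",
    year=2012,
    low_ses=False,
    admission="inpatient",
    weight=7.692,
    diagnoses=("N80.1",),
    procedures=(),
):
    return ClaimRecord(
        patient_id=patient_id,
        age=age,
        sex=sex,
        year=year,
        low_ses=low_ses,
        admission=admission,
        weight=weight,
        diagnoses=frozenset(diagnoses),
        procedures=frozenset(procedures),
    )


@pytest.fixture
def small_dataset():
    """Ten hand-written patient-year records covering both sexes and groups."""
    recs = [
        make_record("P01", 34, diagnoses=("N80.1", "N30.0"), procedures=("SURG_GYN", "URINALYSIS")),
        make_record("P02", 28, diagnoses=("N80.3",), procedures=("RX_GNRH",)),
        make_record("P03", 41, diagnoses=("N80.9",)),  # untreated N80
        make_record("P04", 22, diagnoses=("N30.0",), procedures=("URINALYSIS",)),
        make_record("P05", 37, diagnoses=("D24", "E04.1"), procedures=("MAMMOGRAPHY", "TSH")),
        make_record("P06", 19, diagnoses=("J06.9",)),
        make_record("P07", 30, diagnoses=("K29.7", "M54.5")),
        make_record("P08", 44, diagnoses=("E04.2",), procedures=("TSH",)),
        make_record("P09", 34, sex="M", diagnoses=("N30.0",), procedures=("URINALYSIS",)),
        make_record("P10", 26, admission="outpatient", weight=100.0, diagnoses=("D50.9",), procedures=("HAEMOGLOBIN",)),
    ]
    return ClaimsDataset(recs, provenance="fixture")
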