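from datetime import date, timedelta

import pytest

from admitleak import RecordTable, TestRecord
from admitleak.synthetic import TABLE_COUNTS


def make_record(**overrides) -> TestRecord:
    """A valid inpatient record; override any field."""
    base = dict(
        accession_id="A0000001",
        sex="female",
        encounter_class="inpatient",
        location="5-MEDICINE",
        test_category="viral",
        result_text="Not detected",
        collection_date=date(2014, 3, 10),
        admission_date=date(2014, 3, 9),
        discharge_date=date(2014, 3, 15),
    )
    base.update(overrides)
    return TestRecord(**base)


def make_table(records, provenance="test") -> RecordTable:
    return RecordTable(list(records), provenance=provenance)


@pytest.fixture(scope="session")
def demographic_replica() -> RecordTable:
    """A cohort whose (setting x category x sex) cell counts exactly equal the
    published demographic table of the emulated study (271,769 records)."""
    records = []
    i = 0
    day = date(2013, 6, 1)
    for (cls, cat, sex), count in sorted(TABLE_COUNTS.items()):
        for _ in range(count):
            i += 1
            records.append(
                TestRecord(
                    accession_id=f"R{i:07d}",
                    sex=sex,
                    encounter_class=cls,
                    location="5-MEDICINE" if cls == "inpatient" else "CLINIC",
                    test_category=cat,
                    result_text="POSITIVE",
                    collection_date=day,
                    admission_date=day,
                    discharge_date=day + timedelta(days=1),
                )
            )
    return RecordTable(records, provenance="synthetic")
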