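"""Test-level metadata records and delimited-text I/O.

One :class:`TestRecord` is one clinical laboratory sample accession: the
sample's collection date together with the encounter metadata (care setting,
ward location, patient sex) and the protected admission/discharge dates the
downstream concordance analysis compares it against.

Files are header-bearing CSV (a tab-delimited dialect is auto-detected on
read) with the columns of :data:`COLUMNS`, dates serialized as ISO-8601
``YYYY-MM-DD``. Collection timestamps carrying a time of day are truncated to
the calendar day, because admission dates in hospital systems are recorded to
the day only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

__all__ = [
    "COLUMNS",
    "SEXES",
    "ENCOUNTER_CLASSES",
    "TEST_CATEGORIES",
    "TestRecord",
    "RecordTable",
    "RecordsError",
    "SchemaError",
    "RecordParseError",
    "parse_date",
    "normalize_sex",
    "normalize_encounter_class",
    "read_records",
    "write_records",
]

COLUMNS = (
    "accession_id",
    "sex",
    "encounter_class",
    "location",
    "test_category",
    "result_text",
    "collection_date",
    "admission_date",
    "discharge_date",
)

SEXES = frozenset({"female", "male"})
ENCOUNTER_CLASSES = frozenset({"inpatient", "outpatient", "emergency", "outside"})
TEST_CATEGORIES = frozenset({"bacterial_fungal", "viral"})

# Case-insensitive synonym maps for the categorical fields. Laboratory
# information system exports abbreviate these inconsistently.
_SEX_SYNONYMS = {
    "f": "female",
    "female": "female",
    "m": "male",
    "male": "male",
}

_CLASS_SYNONYMS = {
    "inpatient": "inpatient",
    "ip": "inpatient",
    "outpatient": "outpatient",
    "op": "outpatient",
    "emergency": "emergency",
    "emergency room": "emergency",
    "emergency department": "emergency",
    "er": "emergency",
    "ed": "emergency",
    "outside": "outside",
    "outreach": "outside",
    "reference": "outside",
    "reference lab": "outside",
    "ref lab": "outside",
}

_CATEGORY_SYNONYMS = {
    "bacterial_fungal": "bacterial_fungal",
    "bacterial-fungal": "bacterial_fungal",
    "bacterial/fungal": "bacterial_fungal",
    "bacterial": "bacterial_fungal",
    "fungal": "bacterial_fungal",
    "viral": "viral",
    "virology": "viral",
    "virus": "viral",
}

# Accepted input date layouts; time-of-day, when present, is truncated.
_DATE_FORMATS = (
    "%Y-%m-%d",
    "%Y-%m-%d %H:%M",
    "%Y-%m-%d %H:%M:%S",
    "%Y-%m-%dT%H:%M",
    "%Y-%m-%dT%H:%M:%S",
    "%m/%d/%Y",
    "%m/%d/%Y %H:%M",
)

DateLike = Union[date, str]


class RecordsError(ValueError):
    """Base error for record I/O and validation."""


class SchemaError(RecordsError):
    """Input file is missing a required column."""


class RecordParseError(RecordsError):
    """A field failed strict-mode parsing; carries row number and field."""

    def __init__(self, row: int, field_name: str, value: str):
        self.row = row
        self.field = field_name
        self.value = value
        super().__init__(
            f"row {row}: field {field_name}: cannot parse value {value!r}"
        )


def parse_date(value: DateLike) -> date | None:
    """Parse a calendar date, truncating any time-of-day; None if unparseable."""
    if isinstance(value, datetime):
        return value.date()
    if isinstance(value, date):
        return value
    s = str(value).strip()
    for fmt in _DATE_FORMATS:
        try:
            return datetime.strptime(s, fmt).date()
        except ValueError:
            continue
    return None


def _norm(s: str) -> str:
    return " ".join(str(s).strip().lower().split())


def normalize_sex(value: str) -> str | None:
    return _SEX_SYNONYMS.get(_norm(value))


def normalize_encounter_class(value: str) -> str | None:
    return _CLASS_SYNONYMS.get(_norm(value))


def normalize_test_category(value: str) -> str | None:
    return _CATEGORY_SYNONYMS.get(_norm(value))


@dataclass
class TestRecord:
    """One sample accession's retained metadata.

    Date fields hold :class:`datetime.date` after validation; under lenient
    loading an unparseable raw string is preserved verbatim so the QC cascade
    can count its removal.
    """

    accession_id: str
    sex: str
    encounter_class: str
    location: str
    test_category: str
    result_text: str
    collection_date: DateLike
    admission_date: DateLike
    discharge_date: DateLike

    def copy(self, **changes) -> "TestRecord":
        return replace(self, **changes)

    def is_valid(self) -> bool:
        """True when all kept fields are non-empty, categoricals are in their
        enumerations, and all three dates parse to calendar dates."""
        if not str(self.accession_id).strip():
            return False
        if self.sex not in SEXES:
            return False
        if self.encounter_class not in ENCOUNTER_CLASSES:
            return False
        if self.test_category not in TEST_CATEGORIES:
            return False
        if not str(self.location).strip() or not str(self.result_text).strip():
            return False
        return all(
            parse_date(d) is not None
            for d in (self.collection_date, self.admission_date, self.discharge_date)
        )


@dataclass
class RecordTable:
    """Ordered collection of :class:`TestRecord` with provenance."""

    records: list[TestRecord] = field(default_factory=list)
    provenance: str = "unknown"

    @property
    def row_count(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, keep: Iterable[TestRecord], provenance: str | None = None) -> "RecordTable":
        return RecordTable(list(keep), provenance or self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "accession_id": r.accession_id,
                "sex": r.sex,
                "encounter_class": r.encounter_class,
                "location": r.location,
                "test_category": r.test_category,
                "result_text": r.result_text,
                "collection_date": r.collection_date,
                "admission_date": r.admission_date,
                "discharge_date": r.discharge_date,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(COLUMNS))


def _coerce_field(row_idx: int, name: str, raw: str, strict: bool) -> DateLike:
    """Normalize one field value; raise in strict mode when it cannot be."""
    if name in ("collection_date", "admission_date", "discharge_date"):
        parsed = parse_date(raw)
        if parsed is not None:
            return parsed
        if strict:
            raise RecordParseError(row_idx, name, raw)
        return raw
    if name == "sex":
        norm = normalize_sex(raw)
    elif name == "encounter_class":
        norm = normalize_encounter_class(raw)
    elif name == "test_category":
        norm = normalize_test_category(raw)
    else:
        return raw
    if norm is not None:
        return norm
    if strict:
        raise RecordParseError(row_idx, name, raw)
    return raw


def read_records(path: str | Path, strict: bool = False) -> RecordTable:
    """Read a delimited-text record table.

    Parameters
    ----------
    path:
        CSV or TSV file with a header row naming every :data:`COLUMNS` field.
        The delimiter is auto-detected from the header line.
    strict:
        When True, an unparseable date or out-of-enumeration categorical
        raises :class:`RecordParseError` naming the row and field. When False
        (lenient), the raw string is preserved for the QC cascade to remove;
        no row is ever silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise SchemaError(f"{path}: empty file, no header")
        delimiter = "\t" if "\t" in header_line else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delimiter)
        missing = [c for c in COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        records: list[TestRecord] = []
        for i, row in enumerate(reader, start=1):
            values = {
                name: _coerce_field(i, name, (row.get(name) or "").strip(), strict)
                for name in COLUMNS
            }
            records.append(TestRecord(**values))
    return RecordTable(records, provenance=str(path))


def _date_str(value: DateLike) -> str:
    parsed = parse_date(value)
    return parsed.isoformat() if parsed is not None else str(value)


def write_records(table: RecordTable, path: str | Path) -> Path:
    """Write a record table as CSV with ISO-8601 dates; returns the path."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for r in table.records:
            writer.writerow(
                [
                    r.accession_id,
                    r.sex,
                    r.encounter_class,
                    r.location,
                    r.test_category,
                    r.result_text,
                    _date_str(r.collection_date),
                    _date_str(r.admission_date),
                    _date_str(r.discharge_date),
                ]
            )
    return path
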