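"""Quality-control cascade for clinical test metadata.

Four rules, applied in a fixed order, with every removal accounted for:

1. ``dedup_accession`` — one record per laboratory accession number (first in
   input order wins), collapsing multiple tests from a single sample.
2. ``nonsensical_values`` — drop records with any empty kept field, an
   unparseable date, or an out-of-enumeration sex/encounter class (in real
   exports these are typically staff competency-testing entries).
3. ``collection_outside_window`` — drop records whose collection date falls
   before admission or after discharge; boundary days are retained, since a
   specimen may legitimately be collected on the admission or discharge day.
4. ``reference_lab`` — drop outside (reference laboratory) testing, for which
   an admission date cannot be confidently assigned.

The per-rule counts are order-dependent, so the order is part of the
contract. ``input_count == retained_count + sum(removed_by_rule)`` always.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

from .records import RecordTable, TestRecord, parse_date

__all__ = [
    "QC_RULES",
    "QCReport",
    "dedup_by_accession",
    "remove_nonsensical",
    "remove_outside_window",
    "remove_reference_lab",
    "run_qc",
]

QC_RULES = (
    "dedup_accession",
    "nonsensical_values",
    "collection_outside_window",
    "reference_lab",
)


@dataclass
class QCReport:
    """Per-rule removal accounting for one cascade run."""

    input_count: int
    removed_by_rule: dict[str, int]
    retained_count: int

    def __post_init__(self):
        if self.input_count != self.retained_count + sum(self.removed_by_rule.values()):
            raise ValueError("QCReport counts do not balance")
        if self.input_count < 0 or self.retained_count < 0:
            raise ValueError("QCReport counts must be non-negative")
        if any(v < 0 for v in self.removed_by_rule.values()):
            raise ValueError("QCReport counts must be non-negative")

    @property
    def removed_total(self) -> int:
        return sum(self.removed_by_rule.values())

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "removed_by_rule": dict(self.removed_by_rule),
            "removed_total": self.removed_total,
            "retained_count": self.retained_count,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def dedup_by_accession(table: RecordTable) -> tuple[RecordTable, int]:
    """Keep the first record per accession id; return (table, removed)."""
    seen: set[str] = set()
    kept: list[TestRecord] = []
    for r in table.records:
        if r.accession_id in seen:
            continue
        seen.add(r.accession_id)
        kept.append(r)
    return table.subset(kept), table.row_count - len(kept)


def _coerced(record: TestRecord) -> TestRecord:
    """Record with all three dates as date objects (requires validity)."""
    return record.copy(
        collection_date=parse_date(record.collection_date),
        admission_date=parse_date(record.admission_date),
        discharge_date=parse_date(record.discharge_date),
    )


def remove_nonsensical(table: RecordTable) -> tuple[RecordTable, int]:
    """Drop empty/garbled/out-of-enumeration records; coerce surviving dates."""
    kept = [_coerced(r) for r in table.records if r.is_valid()]
    return table.subset(kept), table.row_count - len(kept)


def remove_outside_window(table: RecordTable) -> tuple[RecordTable, int]:
    """Retain records with admission <= collection <= discharge (inclusive)."""
    kept = []
    for r in table.records:
        c, a, d = parse_date(r.collection_date), parse_date(r.admission_date), \
            parse_date(r.discharge_date)
        if c is None or a is None or d is None:
            raise ValueError(
                f"record {r.accession_id}: unparseable date reached the "
                "date-window rule; run remove_nonsensical first"
            )
        if a <= c <= d:
            kept.append(r)
    return table.subset(kept), table.row_count - len(kept)


def remove_reference_lab(table: RecordTable) -> tuple[RecordTable, int]:
    """Drop outside (reference-lab) encounters."""
    kept = [r for r in table.records if r.encounter_class != "outside"]
    return table.subset(kept), table.row_count - len(kept)


def run_qc(table: RecordTable) -> tuple[RecordTable, QCReport]:
    """Apply the full cascade in order; counts always balance."""
    n_in = table.row_count
    table, n_dup = dedup_by_accession(table)
    table, n_bad = remove_nonsensical(table)
    table, n_win = remove_outside_window(table)
    table, n_ref = remove_reference_lab(table)
    report = QCReport(
        input_count=n_in,
        removed_by_rule={
            "dedup_accession": n_dup,
            "nonsensical_values": n_bad,
            "collection_outside_window": n_win,
            "reference_lab": n_ref,
        },
        retained_count=table.row_count,
    )
    return table, report
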