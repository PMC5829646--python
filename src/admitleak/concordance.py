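"""Collection-vs-admission date concordance: the core imputability statistic.

For every QC-passed sample the offset is the whole number of calendar days
between specimen collection and hospital admission (zero = same-day
collection). The within-k proportion P(offset <= k) — computed overall and
stratified by care setting, test category, patient sex, and inpatient ward —
measures how precisely a protected admission date can be imputed from a
publicly deposited collection date: a within-1-day proportion of 99% means
the admission date is recoverable to +/-1 day for 99% of samples.

Percentages are reported round-half-up to one decimal and proportions to
three decimals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .records import RecordTable, parse_date

__all__ = [
    "DEFAULT_THRESHOLDS",
    "DEFAULT_WARD_PATTERNS",
    "WARD_CATEGORIES",
    "OffsetSummary",
    "DemographicsTable",
    "round_half_up",
    "compute_offsets",
    "summarize",
    "stratify",
    "classify_ward",
    "load_ward_patterns",
    "viral_positive_subset",
    "demographics",
]

#: Day thresholds reported by default: exact, 1 day, 1 week, 1 month,
#: 2 months, half a year, 1 year.
DEFAULT_THRESHOLDS = (0, 1, 7, 30, 60, 180, 365)

WARD_CATEGORIES = ("ICU", "medicine", "obgyn", "surgery", "unclassified")

#: Ordered case-insensitive substring patterns; first match wins. ICU comes
#: first so "MEDICAL ICU" and "SURGICAL ICU" land in ICU, not medicine or
#: surgery. Covers common US ward-naming conventions; anything unmatched is
#: reported as unclassified.
DEFAULT_WARD_PATTERNS: tuple[tuple[str, str], ...] = (
    ("icu", "ICU"),
    ("intensive care", "ICU"),
    ("critical care", "ICU"),
    ("ccu", "ICU"),
    ("ob/gyn", "obgyn"),
    ("obgyn", "obgyn"),
    ("ob-gyn", "obgyn"),
    ("obstetric", "obgyn"),
    ("gynecol", "obgyn"),
    ("labor & delivery", "obgyn"),
    ("labor and delivery", "obgyn"),
    ("l&d", "obgyn"),
    ("maternity", "obgyn"),
    ("antepartum", "obgyn"),
    ("postpartum", "obgyn"),
    ("birth center", "obgyn"),
    ("surg", "surgery"),
    ("operating room", "surgery"),
    ("periop", "surgery"),
    ("ortho", "surgery"),
    ("trauma", "surgery"),
    ("medic", "medicine"),
    ("cardiol", "medicine"),
    ("oncol", "medicine"),
    ("nephrol", "medicine"),
    ("pulmon", "medicine"),
    ("gastro", "medicine"),
    ("hematol", "medicine"),
    ("infectious", "medicine"),
    ("hospitalist", "medicine"),
    ("telemetry", "medicine"),
)

_POSITIVE_RE = re.compile(r"positive", re.IGNORECASE)
_DIGIT_RE = re.compile(r"\d")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero to ``ndigits`` decimals (printed-table style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class OffsetSummary:
    """Integer day offsets of one stratum with cumulative within-k proportions."""

    stratum_label: str
    n: int
    offsets: np.ndarray
    within_k: dict[int, float] = field(default_factory=dict)

    def within(self, k: int) -> float:
        """P(offset <= k), computed from the stored offsets."""
        return float(np.count_nonzero(self.offsets <= k)) / self.n

    def within_pct(self, k: int) -> float:
        """Within-k proportion as a percentage, round-half-up to one decimal."""
        return round_half_up(100.0 * self.within_k.get(k, self.within(k)), 1)


def compute_offsets(table: RecordTable) -> np.ndarray:
    """Per-record collection minus admission date, in whole calendar days.

    Requires a QC-passed table; a negative offset means the date-window rule
    was skipped and raises.
    """
    offsets = np.empty(table.row_count, dtype=np.int64)
    for i, r in enumerate(table.records):
        c = parse_date(r.collection_date)
        a = parse_date(r.admission_date)
        if c is None or a is None:
            raise ValueError(f"record {r.accession_id}: unparseable date; run QC first")
        offsets[i] = (c - a).days
    if table.row_count and offsets.min() < 0:
        raise ValueError("negative day offset encountered; run QC first")
    return offsets


def summarize(
    offsets: Iterable[int],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    label: str = "all",
) -> OffsetSummary:
    """Cumulative within-k proportions of a day-offset multiset."""
    arr = np.asarray(list(offsets) if not isinstance(offsets, np.ndarray) else offsets,
                     dtype=np.int64)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty offset multiset")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    sorted_arr = np.sort(arr)
    n = arr.size
    within = {
        int(k): float(np.searchsorted(sorted_arr, k, side="right")) / n
        for k in thresholds
    }
    return OffsetSummary(stratum_label=label, n=int(n), offsets=arr, within_k=within)


def classify_ward(
    location: str,
    mapping: Sequence[tuple[str, str]] = DEFAULT_WARD_PATTERNS,
) -> str:
    """Map a free-text ward/clinic string to a ward category.

    Ordered case-insensitive substring match, first pattern wins;
    ``unclassified`` when nothing matches.
    """
    loc = str(location).lower()
    for pattern, category in mapping:
        if pattern.lower() in loc:
            return category
    return "unclassified"


def load_ward_patterns(path: str | Path) -> tuple[tuple[str, str], ...]:
    """Load an ordered ward-pattern table from YAML ([[pattern, category], ...])."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    patterns = tuple((str(p), str(c)) for p, c in raw)
    for _, category in patterns:
        if category not in WARD_CATEGORIES:
            raise ValueError(f"unknown ward category {category!r}")
    return patterns


_STRATUM_FIELDS = ("sex", "encounter_class", "test_category", "ward")


def _field_value(record, name: str, ward_patterns) -> str:
    if name == "ward":
        return classify_ward(record.location, ward_patterns)
    return getattr(record, name)


def stratify(
    table: RecordTable,
    by: Sequence[str],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    ward_patterns: Sequence[tuple[str, str]] = DEFAULT_WARD_PATTERNS,
) -> dict[tuple[str, ...], OffsetSummary]:
    """One OffsetSummary per observed stratum combination (n=0 strata omitted).

    ``by`` lists TestRecord categoricals; the pseudo-field ``ward`` classifies
    the location string through the ward-pattern table.
    """
    for name in by:
        if name not in _STRATUM_FIELDS:
            raise KeyError(f"unknown stratification field {name!r}")
    offsets = compute_offsets(table)
    groups: dict[tuple[str, ...], list[int]] = {}
    for i, r in enumerate(table.records):
        key = tuple(_field_value(r, name, ward_patterns) for name in by)
        groups.setdefault(key, []).append(i)
    out = {}
    for key in sorted(groups):
        idx = np.array(groups[key], dtype=np.int64)
        label = ",".join(f"{f}={v}" for f, v in zip(by, key))
        out[key] = summarize(offsets[idx], thresholds, label=label)
    return out


def viral_positive_subset(table: RecordTable) -> RecordTable:
    """Viral records whose result text contains 'positive' or a quantity.

    Virology result coding rarely permits restricting to positives directly;
    this lexical rule keeps viral records whose free-text result contains the
    token "positive" (case-insensitive) or any digit run (viral loads such as
    "3.2E4 copies/mL" or log10 values). The rule is purely lexical: it does
    not attempt to parse negations.
    """
    kept = [
        r
        for r in table.records
        if r.test_category == "viral"
        and (_POSITIVE_RE.search(str(r.result_text)) or _DIGIT_RE.search(str(r.result_text)))
    ]
    return table.subset(kept)


@dataclass
class DemographicsTable:
    """Cohort composition: cell counts with derived marginals and percentages."""

    by_class_category: dict[tuple[str, str], int]
    by_category_class_sex: dict[tuple[str, str, str], int]
    total: int

    def class_marginal(self, encounter_class: str) -> int:
        return sum(v for (cls, _), v in self.by_class_category.items()
                   if cls == encounter_class)

    def category_marginal(self, category: str) -> int:
        return sum(v for (_, cat), v in self.by_class_category.items()
                   if cat == category)

    def sex_marginal(self, sex: str) -> int:
        return sum(v for (_, _, s), v in self.by_category_class_sex.items()
                   if s == sex)

    def pct(self, count: int) -> float:
        """Share of the cohort as a percentage, round-half-up to one decimal."""
        if self.total == 0:
            return 0.0
        return round_half_up(100.0 * count / self.total, 1)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"encounter_class": cls, "test_category": cat, "sex": sex, "count": v}
            for (cat, cls, sex), v in sorted(self.by_category_class_sex.items())
        ]
        return pd.DataFrame(rows, columns=["encounter_class", "test_category", "sex", "count"])


def demographics(table: RecordTable) -> DemographicsTable:
    """Cell counts by (setting x category) and (category x setting x sex)."""
    by_cc: dict[tuple[str, str], int] = {}
    by_ccs: dict[tuple[str, str, str], int] = {}
    for r in table.records:
        by_cc[(r.encounter_class, r.test_category)] = (
            by_cc.get((r.encounter_class, r.test_category), 0) + 1
        )
        key = (r.test_category, r.encounter_class, r.sex)
        by_ccs[key] = by_ccs.get(key, 0) + 1
    return DemographicsTable(
        by_class_category=by_cc,
        by_category_class_sex=by_ccs,
        total=table.row_count,
    )
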