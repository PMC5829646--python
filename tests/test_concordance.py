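from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from admitleak import (
    classify_ward,
    compute_offsets,
    default_config,
    demographics,
    generate_cohort,
    round_half_up,
    stratify,
    summarize,
    viral_positive_subset,
)
from admitleak.concordance import DEFAULT_WARD_PATTERNS, load_ward_patterns
from admitleak.synthetic import CONTAMINATION_MODES
from conftest import make_record, make_table


# --- offsets ---------------------------------------------------------------

@pytest.mark.parametrize(
    "collection,admission,expected",
    [
        (date(2014, 3, 9), date(2014, 3, 9), 0),
        (date(2014, 3, 10), date(2014, 3, 9), 1),
        (date(2015, 1, 5), date(2014, 12, 29), 7),  # across a year boundary
    ],
)
def test_offset_is_calendar_day_difference(collection, admission, expected):
    table = make_table(
        [make_record(collection_date=collection, admission_date=admission,
                     discharge_date=collection)]
    )
    assert compute_offsets(table).tolist() == [expected]


def test_negative_offset_signals_skipped_qc():
    table = make_table([make_record(collection_date=date(2014, 3, 1))])
    with pytest.raises(ValueError, match="negative"):
        compute_offsets(table)


# --- summarize -------------------------------------------------------------

def test_summarize_counts_directly():
    s = summarize([0, 0, 1, 5], thresholds=[0, 1, 7])
    assert s.within_k == {0: 0.5, 1: 0.75, 7: 1.0}
    assert s.n == 4


def test_summarize_all_zero_offsets():
    s = summarize([0] * 10)
    assert all(v == 1.0 for v in s.within_k.values())


def test_summarize_rejects_empty_and_unsorted():
    with pytest.raises(ValueError):
        summarize([])
    with pytest.raises(ValueError):
        summarize([0, 1], thresholds=[7, 0])


def test_viral_positive_worked_example_proportions():
    """16,434 samples with 14,133 same-day and 14,994 within one day give
    86.0% and 91.2% — the printed subset arithmetic."""
    offsets = [0] * 14_133 + [1] * (14_994 - 14_133) + [2] * (16_434 - 14_994)
    s = summarize(offsets, thresholds=[0, 1])
    assert round(s.within_k[0], 3) == 0.860
    assert round(s.within_k[1], 3) == 0.912
    assert s.within_pct(0) == 86.0
    assert s.within_pct(1) == 91.2


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=400), min_size=1, max_size=60))
def test_within_k_monotone_and_bounded(offsets):
    s = summarize(offsets)
    values = [s.within_k[k] for k in sorted(s.within_k)]
    assert all(0.0 <= v <= 1.0 for v in values)
    assert all(a <= b for a, b in zip(values, values[1:]))
    assert s.within(max(offsets)) == 1.0


# --- stratify --------------------------------------------------------------

def test_stratify_two_singleton_strata():
    table = make_table(
        [
            make_record(accession_id="A1", sex="female"),
            make_record(accession_id="A2", sex="male"),
        ]
    )
    out = stratify(table, ["sex"])
    assert set(out) == {("female",), ("male",)}
    assert all(s.n == 1 for s in out.values())


def test_stratified_counts_partition_parent():
    cfg = default_config(n_samples=4000, seed=6).replace(
        contamination={m: 0.0 for m in CONTAMINATION_MODES}
    )
    table = generate_cohort(cfg)
    for fields in (["sex"], ["encounter_class", "test_category"], ["ward"]):
        out = stratify(table, fields)
        assert sum(s.n for s in out.values()) == table.row_count


def test_stratify_unknown_field_raises():
    with pytest.raises(KeyError):
        stratify(make_table([make_record()]), ["favorite_color"])


# --- ward classification ---------------------------------------------------

@pytest.mark.parametrize(
    "location,expected",
    [
        ("MEDICAL ICU", "ICU"),
        ("SURGICAL ICU", "ICU"),
        ("Labor & Delivery", "obgyn"),
        ("OB/GYN WARD", "obgyn"),
        ("ORTHOPEDIC SURGERY", "surgery"),
        ("CARDIOLOGY WARD", "medicine"),
        ("5-MEDICINE", "medicine"),
        ("6-EAST", "unclassified"),
    ],
)
def test_default_ward_mapping(location, expected):
    assert classify_ward(location) == expected


def test_first_matching_pattern_wins():
    mapping = (("medical", "medicine"), ("icu", "ICU"))
    assert classify_ward("MEDICAL ICU", mapping) == "medicine"


def test_ward_patterns_loadable_from_yaml(tmp_path):
    path = tmp_path / "wards.yaml"
    path.write_text("- [icu, ICU]\n- [ward 9, medicine]\n")
    patterns = load_ward_patterns(path)
    assert classify_ward("WARD 9", patterns) == "medicine"
    (tmp_path / "bad.yaml").write_text("- [x, nursery]\n")
    with pytest.raises(ValueError, match="nursery"):
        load_ward_patterns(tmp_path / "bad.yaml")


# --- viral positive subset -------------------------------------------------

@pytest.mark.parametrize(
    "result,kept",
    [
        ("POSITIVE", True),
        ("Positive - confirmed", True),
        ("3.2E4 copies/mL", True),
        ("log10 5.1", True),
        ("Not detected", False),
        ("NEGATIVE", False),
    ],
)
def test_viral_positive_rule_is_lexical(result, kept):
    table = make_table([make_record(result_text=result)])
    assert (viral_positive_subset(table).row_count == 1) is kept


def test_bacterial_records_never_in_viral_subset():
    table = make_table(
        [make_record(test_category="bacterial_fungal", result_text="POSITIVE")]
    )
    assert viral_positive_subset(table).row_count == 0


# --- demographics ----------------------------------------------------------

def test_demographic_marginals_reproduce_published_arithmetic(demographic_replica):
    demo = demographics(demographic_replica)
    assert demo.total == 271_769
    assert demo.class_marginal("emergency") == 2_197 + 29_964 == 32_161
    assert demo.sex_marginal("female") == (967 + 6_976 + 24_883) + (
        15_516 + 33_391 + 57_237
    ) == 138_970
    assert demo.pct(demo.class_marginal("emergency")) == 11.8
    assert demo.pct(demo.sex_marginal("female")) == 51.1
    total_cells = sum(demo.by_category_class_sex.values())
    assert total_cells == demo.total


def test_empty_table_demographics_all_zero():
    demo = demographics(make_table([]))
    assert demo.total == 0
    assert demo.class_marginal("inpatient") == 0
    assert demo.pct(0) == 0.0


# --- rounding convention ---------------------------------------------------

@pytest.mark.parametrize(
    "x,nd,expected",
    [(0.05, 1, 0.1), (2.25, 1, 2.3), (51.135, 1, 51.1), (86.0, 1, 86.0),
     (0.8599853961299745, 3, 0.86)],
)
def test_round_half_up(x, nd, expected):
    assert round_half_up(x, nd) == expected
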