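"""End-to-end imputability risk report.

Orchestrates one run: load or simulate a cohort, apply the QC cascade,
tabulate demographics, compute stratified within-k offset summaries, run the
configured two-sample comparisons, and assemble a machine-readable
:class:`RiskReport`. The headline block (exact match, within 1 day, within 30
days — overall and per care setting) is pulled directly from the summaries,
never recomputed, so the report cannot drift from its own tables.

Reports serialize with sorted keys and fixed float formatting so that two
runs with the same config and seed produce byte-identical JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .concordance import (
    DEFAULT_THRESHOLDS,
    DemographicsTable,
    OffsetSummary,
    compute_offsets,
    demographics,
    stratify,
    summarize,
    viral_positive_subset,
)
from .qc import QCReport, run_qc
from .records import RecordTable, read_records
from .stats import format_p, ks_two_sample, prop_two_sample
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["RiskReport", "run_pipeline", "render_report", "DEFAULT_STRATA"]

logger = logging.getLogger("admitleak")

#: Stratifications computed by default; a stratum tuple containing "ward" is
#: evaluated on the inpatient subset only, as ward structure is an inpatient
#: concept.
DEFAULT_STRATA: tuple[tuple[str, ...], ...] = (
    ("encounter_class",),
    ("test_category",),
    ("encounter_class", "test_category"),
    ("sex",),
    ("ward",),
)

_HEADLINE_KEYS = {
    "exact_match_pct": 0,
    "within_1_day_pct": 1,
    "within_30_days_pct": 30,
}


@dataclass
class RiskReport:
    qc: QCReport
    demographics: DemographicsTable
    summaries: list[OffsetSummary]
    tests: list[dict] = field(default_factory=list)
    headline: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "qc": self.qc.to_dict(),
            "demographics": {
                "total": self.demographics.total,
                "by_encounter_class_test_category": {
                    f"{cls}/{cat}": v
                    for (cls, cat), v in sorted(self.demographics.by_class_category.items())
                },
                "by_test_category_encounter_class_sex": {
                    f"{cat}/{cls}/{sex}": v
                    for (cat, cls, sex), v in sorted(
                        self.demographics.by_category_class_sex.items()
                    )
                },
            },
            "summaries": [
                {
                    "stratum": s.stratum_label,
                    "n": s.n,
                    "within_k": {str(k): round(v, 6) for k, v in sorted(s.within_k.items())},
                }
                for s in self.summaries
            ],
            "tests": [dict(t) for t in self.tests],
            "headline": self.headline,
        }


def _headline_block(summary: OffsetSummary) -> dict:
    return {name: summary.within_pct(k) for name, k in _HEADLINE_KEYS.items()}


def _default_tests(table: RecordTable, offsets) -> list[dict]:
    """The comparisons mirroring the study: category KS, sex KS, sex
    same-day proportion test, and viral positives vs all viral testing."""
    tests: list[dict] = []
    by_cat = {}
    by_sex = {}
    for i, r in enumerate(table.records):
        by_cat.setdefault(r.test_category, []).append(i)
        by_sex.setdefault(r.sex, []).append(i)

    def _ks(label, idx1, idx2):
        res = ks_two_sample(offsets[idx1], offsets[idx2])
        tests.append(
            {
                "label": label,
                "type": "ks",
                "statistic": round(res.D, 6),
                "p_value": res.p_value,
                "p_display": format_p(res.p_value),
                "n1": res.n1,
                "n2": res.n2,
            }
        )

    if {"bacterial_fungal", "viral"} <= set(by_cat):
        _ks("bacterial_fungal vs viral", by_cat["bacterial_fungal"], by_cat["viral"])
    if {"female", "male"} <= set(by_sex):
        _ks("female vs male", by_sex["female"], by_sex["male"])
        f_idx, m_idx = by_sex["female"], by_sex["male"]
        x1 = int((offsets[f_idx] == 0).sum())
        x2 = int((offsets[m_idx] == 0).sum())
        res = prop_two_sample(x1, len(f_idx), x2, len(m_idx))
        tests.append(
            {
                "label": "same-day proportion, female vs male",
                "type": "prop",
                "statistic": round(res.z, 6),
                "p1": round(res.p1, 6),
                "p2": round(res.p2, 6),
                "p_value": res.p_value,
                "p_display": format_p(res.p_value),
                "n1": res.n1,
                "n2": res.n2,
            }
        )
    if "viral" in by_cat:
        positives = viral_positive_subset(table)
        if positives.row_count:
            pos_offsets = compute_offsets(positives)
            res = ks_two_sample(pos_offsets, offsets[by_cat["viral"]])
            tests.append(
                {
                    "label": "viral positives vs all viral",
                    "type": "ks",
                    "statistic": round(res.D, 6),
                    "p_value": res.p_value,
                    "p_display": format_p(res.p_value),
                    "n1": res.n1,
                    "n2": res.n2,
                }
            )
    return tests


def run_pipeline(
    source: RecordTable | SyntheticConfig | str | Path,
    strata: Sequence[Sequence[str]] = DEFAULT_STRATA,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    with_tests: bool = True,
) -> RiskReport:
    """Run simulate/load -> QC -> concordance -> comparisons.

    ``source`` is a record table, a synthetic-cohort config (simulated here,
    seeded by its own ``seed``), or a path to a delimited record file (read
    leniently; QC removes what does not validate). Deterministic given
    (source, seed).
    """
    if isinstance(source, SyntheticConfig):
        table = generate_cohort(source)
    elif isinstance(source, (str, Path)):
        table = read_records(source, strict=False)
    else:
        table = source
    logger.info("input: %d records (%s)", table.row_count, table.provenance)

    clean, qc_report = run_qc(table)
    logger.info(
        "qc: removed %d of %d, retained %d",
        qc_report.removed_total, qc_report.input_count, qc_report.retained_count,
    )
    demo = demographics(clean)
    offsets = compute_offsets(clean)

    summaries: list[OffsetSummary] = [summarize(offsets, thresholds, label="all")]
    inpatient = clean.subset([r for r in clean.records if r.encounter_class == "inpatient"])
    for fields_ in strata:
        fields_ = tuple(fields_)
        base = inpatient if "ward" in fields_ else clean
        if base.row_count == 0:
            continue
        for s in stratify(base, fields_, thresholds).values():
            if "ward" in fields_:
                s.stratum_label = "inpatient," + s.stratum_label
            summaries.append(s)
    logger.info("concordance: %d stratum summaries", len(summaries))

    by_label = {s.stratum_label: s for s in summaries}
    headline = {"overall": _headline_block(by_label["all"]), "by_encounter_class": {}}
    for cls in ("emergency", "inpatient", "outpatient"):
        s = by_label.get(f"encounter_class={cls}")
        if s is not None:
            headline["by_encounter_class"][cls] = _headline_block(s)

    tests = _default_tests(clean, offsets) if with_tests else []
    return RiskReport(qc=qc_report, demographics=demo, summaries=summaries,
                      tests=tests, headline=headline)


def render_report(report: RiskReport, outdir: str | Path, plot: bool = False) -> list[Path]:
    """Write report.json plus tidy demographics/summaries/tests CSVs.

    With ``plot=True`` also writes a cumulative-curve figure (requires
    matplotlib).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    json_path = outdir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths.append(json_path)

    demo_path = outdir / "demographics.csv"
    report.demographics.to_frame().to_csv(demo_path, index=False)
    paths.append(demo_path)

    rows = [
        {"stratum": s.stratum_label, "n": s.n, "k": k, "proportion": round(v, 6)}
        for s in report.summaries
        for k, v in sorted(s.within_k.items())
    ]
    summ_path = outdir / "summaries.csv"
    pd.DataFrame(rows, columns=["stratum", "n", "k", "proportion"]).to_csv(
        summ_path, index=False
    )
    paths.append(summ_path)

    test_cols = ["label", "type", "statistic", "p_value", "p_display", "n1", "n2"]
    tests_path = outdir / "tests.csv"
    pd.DataFrame(report.tests, columns=test_cols).to_csv(tests_path, index=False)
    paths.append(tests_path)

    if plot:
        paths.append(_plot_curves(report, outdir / "cumulative_curves.png"))
    return paths


def _plot_curves(report: RiskReport, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(7, 5))
    for s in report.summaries:
        if "," in s.stratum_label and not s.stratum_label.startswith("inpatient,"):
            continue
        xs = np.sort(np.unique(s.offsets))
        ys = [s.within(int(k)) for k in xs]
        ax.step(xs + 1, ys, where="post", label=f"{s.stratum_label} (n={s.n})")
    ax.set_xscale("log")
    ax.set_xlabel("days between collection and admission (+1, log scale)")
    ax.set_ylabel("cumulative proportion of samples")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
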