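# admitleak

How precisely can a protected hospital **admission date** be imputed from a
publicly deposited specimen **collection date**?

Pathogen sequences deposited in public databases usually carry a collection
date, because phylodynamic models need temporal resolution finer than a
year. But in US HIPAA Safe Harbor terms, admission and discharge dates at
finer-than-year resolution are protected health information. If collection
and admission dates almost always coincide, depositing the collection date
effectively releases the admission date. `admitleak` is a library (with a
thin CLI) for clinical laboratories, IRB statisticians and phylodynamics
practitioners who want to quantify that leakage on their own test-level
metadata — or, since such data cannot be shared, on a synthetic cohort that
emulates it.

## The statistic

For each QC-passed sample, the offset is the whole number of calendar days
between collection and admission,

    d_i = collection_date_i − admission_date_i  (days, d_i ≥ 0 after QC),

and the imputability measure is the empirical cumulative within-k
proportion

    F̂(k) = #{i : d_i ≤ k} / n,

reported at k = 0, 1, 7, 30, 60, 180, 365 days, overall and stratified by
care setting (inpatient / outpatient / emergency), test category
(bacterial–fungal / viral), patient sex, and inpatient ward (ICU / medicine /
OB-Gyn / surgery, classified from the free-text location). F̂(0) is the
probability the admission date is recoverable *exactly* from the collection
date alone. Strata are compared with a two-sample Kolmogorov–Smirnov test
(D = sup_t |F̂₁(t) − F̂₂(t)|, asymptotic p at effective size n₁n₂/(n₁+n₂))
and a pooled two-proportion z-test at a single threshold, with Bonferroni
adjustment for families of tests.

The pipeline is: delimited-text record I/O → a four-rule QC cascade with
full removal accounting (accession dedup, nonsensical values, collection
outside the admission–discharge window, reference-lab testing) → offset
concordance → statistical comparisons → a machine-readable risk report.

## Worked example

```python
from admitleak import (default_config, generate_cohort, run_qc,
                       compute_offsets, summarize, stratify)

table, _ = run_qc(generate_cohort(default_config(n_samples=50_000, seed=11)))
offsets = compute_offsets(table)
print("exact-match %:", summarize(offsets).within_pct(0))
for s in stratify(table, ["encounter_class"], (0, 1, 30)).values():
    print(s.stratum_label, s.n, [s.within_pct(k) for k in (0, 1, 30)])
```

prints

```
exact-match %: 67.5
encounter_class=emergency 5662 [86.8, 99.3, 100.0]
encounter_class=inpatient 16730 [16.3, 23.2, 93.1]
encounter_class=outpatient 25358 [96.9, 99.6, 100.0]
```

Read: across the whole synthetic cohort the collection date *equals* the
admission date for 67.5% of samples; knowing additionally that a sample came
from outpatient or emergency testing pins the admission date to within one
day more than 99% of the time, while inpatient sampling spreads over the
stay and only the one-month window approaches certainty. These are the
generator's calibrated defaults, which emulate the per-setting concordance
of a large academic laboratory's 271,769-sample testing history.

The same run from the shell:

```
admitleak run --n 50000 --seed 11 --out results/
```

writes `report.json`, `demographics.csv`, `summaries.csv` and `tests.csv`.
Each script in `examples/` demonstrates one capability end to end.

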