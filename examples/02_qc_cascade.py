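"""Run the four-rule QC cascade and reconcile it with the injection ledger.

Each contaminated record in the synthetic cohort violates exactly one rule,
so the per-rule removal counts can be checked against what was injected.
"""

from admitleak import default_config, generate_cohort, run_qc

cfg = default_config(n_samples=10_000, seed=3)
table, ledger = generate_cohort(cfg, with_ledger=True)
clean, report = run_qc(table)

print(f"input records:    {report.input_count}")
for rule, removed in report.removed_by_rule.items():
    print(f"  removed by {rule:<26} {removed:>4}")
print(f"retained:         {report.retained_count}")
print(f"\ninjection ledger: {ledger}")
# dedup matches duplicate_accession; nonsensical matches blank+garbled;
# the date-window rule matches before+after; reference_lab matches outside.
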