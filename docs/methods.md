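# Methods

## Problem and model

A clinical laboratory's test-level metadata links each specimen accession to
a collection date, a care setting, a ward location, the patient's sex, and
the protected admission/discharge dates of the encounter. `admitleak`
quantifies how much of the protected admission date leaks through the
collection date via the day offset `d = collection − admission` and its
cumulative within-k distribution `F̂(k) = P(d ≤ k)`, overall and by stratum.
Everything downstream of record loading treats dates at calendar-day
resolution: collection timestamps are truncated (not rounded) to the day,
because admission dates in hospital systems are recorded to the day only, so
sub-day precision in the offset would be spurious.

## QC cascade

Four rules run in a fixed order — accession dedup (first record in input
order wins), nonsensical-value removal (empty kept field, unparseable date,
out-of-enumeration sex or encounter class), date-window removal (retain
`admission ≤ collection ≤ discharge`, boundaries inclusive, since same-day
collection is the modal case), reference-lab removal (`outside`
encounters, whose admission dates cannot be assigned). Per-rule counts are
order-dependent, so the order is part of the contract, and
`input = retained + Σ removed` is enforced structurally by `QCReport`.
First-wins dedup is a deterministic choice among several defensible ones;
which same-accession row a laboratory system keeps is generally unspecified.
Staff/competency-testing artifacts are not a separate rule: in practice they
surface as nonsensical values or impossible date windows and are counted
under rules 2–3.

## Synthetic cohort generator

Real admission-date-bearing metadata is PHI and is not shipped; the
generator produces cohorts whose *structure* matches the study setting the
package emulates, so every pipeline stage is testable.

* **Mixture.** Stratum = (encounter class × test category × sex), drawn from
  weights proportional to the emulated study's demographic cell counts
  (271,769 samples: 11.8% emergency, 35.0% inpatient, 53.1% outpatient).
* **Offset law.** Per (class, category): `d = 0` with probability `p_zero`,
  else `d ~ Geometric(tail_geom_p)` on {1, 2, ...}. Defaults are calibration
  targets, not fitted values: `p_zero` = 0.867 (emergency), 0.960/0.974
  (outpatient bacterial/viral), 0.220/0.154 (inpatient bacterial/viral);
  tail parameters are solved from the within-1-day anchors for
  emergency/outpatient (≥99.5%) and the within-30-day anchors for inpatient
  (91.5%/93.0%). The geometric tail is the simplest single-parameter law
  that can meet those anchor points; it is memoryless, which real sampling
  schedules are not.
* **No sex-specific law.** The female–male concordance gap emerges
  compositionally: female samples concentrate in outpatient viral testing
  (57,237 vs 30,680), where same-day collection dominates. The mixture alone
  reproduces an exact-match gap of ≈72 vs ≈62% and a sex KS D near 0.09.
* **Stays.** Inpatient stay ~ 1 + Geometric mean-7-days law (tertiary-care
  average stays run about a week); emergency/outpatient stays are geometric
  on {0, 1, ...} with means 1 and 0.5 days, the point mass at zero playing
  the short-stay (same-day discharge) rule. The generator draws the offset
  first and sets `stay = max(offset, stay draw)`: this enforces
  `admission ≤ collection ≤ discharge` by construction, keeps the record
  count exact, and — unlike truncating the offset at an independently drawn
  stay — leaves `p_zero` exactly equal to the marginal same-day probability,
  which is what the parameter-recovery tests verify. The cost is that stays
  conditional on long offsets are lengthened; stay length itself is not an
  analysis target.
* **Results text.** Viral results are rendered positive (a "positive" token
  or a viral-load quantity) with class-dependent probability (0.156
  outpatient, 0.025 elsewhere), so positives concentrate in the outpatient
  setting (~83% of positives) and the positives-vs-all-viral comparison has
  the structure seen in practice (chronic-infection viral-load monitoring
  happens in clinics). Bacterial/fungal records are positive isolates by
  construction.
* **Contamination.** Each dirty mode — blank field, garbled date string,
  collection before admission, collection after discharge, outside-class,
  duplicate accession — is injected at `round(rate × n)` records (exact
  counts, not sampled), each violating exactly one QC rule; the returned
  ledger is the oracle for QC accounting tests. Default rates total 4.5%,
  near the 5.0% removal rate of the emulated study. Dirty records are
  appended after the clean block; duplicates therefore always follow their
  originals, making first-wins dedup reproducible.
* **Reproducibility.** One `numpy` Generator seeded from the config; equal
  configs give identical cohorts byte-for-byte.

What the generator does **not** model: seasonality, pathogen identity,
repeat-patient correlation, ward-specific offset laws (ward labels are drawn
independently of the offset), or linkage to any real individual. Passing
tests on synthetic cohorts therefore demonstrate the pipeline's
correctness and calibration under the configured laws, not the empirical
offset distribution of any particular hospital.

## Statistics

* **KS.** D is computed exactly over the pooled support via sorted
  searchsorted; the two-sided p-value uses the asymptotic Kolmogorov
  distribution `Q(λ) = 2 Σ (−1)^{k−1} e^{−2k²λ²}` (own alternating series,
  cross-checked against `scipy.special.kolmogorov`) at
  `λ = sqrt(n₁n₂/(n₁+n₂))·D` — the classical large-sample formula, as R's
  `ks.test` uses above its exact-regime cutoff. All comparisons of interest
  here involve n in the thousands. Integer day offsets are heavily tied;
  under ties this p-value is conservative. A tie-free calibration check
  (uniform continuous nulls, 4,000 pairs of n=500) shows rejection ≈ 0.05 at
  α=0.05, while the same check on the widest configured integer offset law
  gives ≈ 0.028 — the conservatism is a property of applying the asymptotic
  distribution to tied data, not an implementation defect, and the
  discrete-law calibration test documents it.
* **Proportion test.** Uncorrected pooled two-sample z with two-sided normal
  p (via `erfc`); a Yates-corrected variant is available but off by default —
  with the sample sizes this package targets the correction is negligible,
  and the uncorrected pooled z is the simplest defensible form.
  Degenerate pooled proportions (0 or 1) return p = 1 with a flag rather
  than dividing by zero.
* **Bonferroni.** `min(1, p·m)`, `m` at least the family size.
* **Rendering.** p-values below 2.2e-16 display as "< 2.2e-16", the common
  double-precision reporting floor.

## Rounding and report conventions

Percentages are round-half-up to one decimal; proportions to three decimals
(six in serialized JSON/CSV). The report's headline block is copied from the
corresponding stratum summaries, never recomputed, and reports serialize
with sorted keys and fixed formatting so identical (config, seed) runs are
byte-identical.

## Problem sizes

Default analysis runs use 100,000-record cohorts, which make binomial
standard errors on per-stratum same-day proportions small enough for 3-SE
recovery checks while keeping a full pipeline run in seconds; test-suite
fixtures use 2,000–10,000 records except where a property explicitly
concerns large-sample behaviour. The exhaustive KS brute-force equivalence
check covers all multiset pairs of size ≤ 8 over {0,1,2,3}; null-calibration
simulations use 4,000–10,000 pairs of n=500.

## Known limitations

* The ward-pattern table is an ordered substring map covering common US
  ward-naming conventions; any unmatched location is reported as
  `unclassified` rather than guessed. Institutions should supply their own
  mapping (YAML, first match wins).
* The viral-positive rule is purely lexical ("positive" token or any digit
  run); negated phrases containing digits (e.g. "HSV-2 not detected") are
  retained. Deliberate: result coding varies too much for reliable negation
  parsing, and the rule is stated as a lexical extraction.
* Offsets are non-negative by QC construction; the package does not model
  pre-admission (e.g. outpatient-to-admission) sampling paths.
* Discharge dates are carried and enforced by QC but not analyzed; leakage
  estimates are therefore a lower bound on what collection dates reveal.
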