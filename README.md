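# cutscan

Non-median dichotomization of a continuous biomarker by percentile cut-off
scanning, with permutation-based false-discovery control.

## The problem

Survival biomarker studies usually split a cohort at the *median* of a
continuous variable (gene expression, most often) and compare the two
halves. That choice maximizes group sizes but assumes the prognostically
distinct subgroup is half the population. Many real subgroups are not: a
gene overexpressed in the top 25% of patients defines a 75/25 split, and a
median cut dilutes it beyond recognition. `cutscan` is for analysts who
suspect such a subgroup: it scans **every** percentile split (1–99%),
scores each with an optimization test, and returns the minimum-p cut-off —
together with the machinery that keeps a scanned minimum honest.

## The method

For a trait x₁…xₙ, each integer percentile c defines a split: the
⌊c·n/100⌋ lowest-ranked samples versus the rest. Each split is scored by

* **Cox mode** — Cox proportional hazards with the single indicator
  z = 1(high): h(t|z) = h₀(t) e^{βz}; Wald p with Efron tie handling,
  HR = e^β (HR > 1 ⇒ high group worse). Search range 10–90% by default so
  neither subgroup is vanishingly small.
* **Fisher mode** — two-sided Fisher's exact test of the split against a
  fixed binary status (for co-expression screening), full 1–99% range.

Because the minimum of ~80 correlated p-values is anti-conservative, the
chosen cut-off is certified by:

* **Resampling** — 100 subsamples of 70% of patients, redrawn without
  replacement; recurring clusters of per-subsample optima indicate how
  many distinct subgroups exist (1 recurring cluster ⇒ two groups,
  2 ⇒ low/inter/high).
* **Permutation FDR** — B re-pairings of trait and outcome (default 1000),
  full rescan each: `fdr_ac` = fraction of permutations beating the
  observed p *at the same cut*; `fdr_range` = fraction whose *best in-range*
  p beats it (a min-p multiplicity-adjusted empirical p-value). Floor 1/B.

A genome-wide Fisher mode scans every gene of a matrix against a fixed
status and filters genes whose optimal cut lies in a window (default
75 ± 15%) into a co-expression signature. A synthetic-cohort generator
(mixture expression + planted rank-quantile hazard jump) makes the whole
pipeline testable end to end. See `docs/methods.md` for the full model.

## Worked example

Simulate a 200-patient cohort whose hazard jumps (HR 2.5) above the 75th
expression percentile, then scan and certify it:

```bash
cutscan simulate --n 200 --seed 7 --out sim/
cutscan scan --expression sim/expression.tsv --gene sim_gene \
             --clinical sim/clinical.csv \
             --n-permutations 100 --seed 3 --out run/
```

The run prints (and writes to `run/summary.json`):

```json
{
  "trait": "sim_gene",
  "test_kind": "coxph",
  "n": 200,
  "optimal_percent": 76,
  "p": 5.349233471657488e-13,
  "effect": 3.9536290060514543,
  "effect_ci": [2.721738230838469, 5.743088053209294],
  "median_p": 0.00018338825501685704,
  "search_range": [10, 90],
  "fdr_ac": 0.01,
  "fdr_range": 0.01,
  "n_permutations": 100,
  "n_subgroups": 2,
  "robust_flag": true,
  "recurring_clusters": [[76.0, 100]]
}
```

Reading it: the best split is at the **76th percentile** (the planted cut
was 75), where the high quarter of patients has HR ≈ 3.95 versus the rest
at p ≈ 5×10⁻¹³ — four orders of magnitude stronger than the median split
(p ≈ 1.8×10⁻⁴) on the same cohort. All 100 subsample optima land in one
cluster at 76% (`n_subgroups = 2`: a single boundary), and no permutation
out of 100 produced any in-range p as small as the observed one
(`fdr_range` = 1/B = 0.01), so the cut-off is certified. The run directory
also holds the scan table (`scan.csv`), KM curves and HRs, and four
figures: the scan plot, the expression boxplot with >2·MAD outliers, the
resampled scan plot, and the KM plot at the chosen cut.

The same engine is available as a library:

```python
from cutscan import (SyntheticSpec, gen_survival_cohort,
                     scan_cutoffs, find_optimal, permutation_fdr)
trait, outcome = gen_survival_cohort(SyntheticSpec(n=300, seed=1))
best = find_optimal(scan_cutoffs(trait, outcome))
fdr = permutation_fdr(trait, outcome, n_permutations=1000, seed=1)
```

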