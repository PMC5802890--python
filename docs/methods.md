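# Methods

## The problem: dichotomization bias and rare subgroups

Clinical biomarker studies routinely dichotomize a continuous per-sample
variable — most often the expression of one gene — and compare outcomes
between the resulting groups. The conventional median split maximizes power
for a *balanced* difference but is blind to prognostically distinct
subgroups that make up much less (or more) than half of the cohort: a
high-risk 15% minority is diluted into the upper half and its signal lost.
Scanning *all* cut-offs and keeping the best one finds such subgroups, but
the minimum of 81–99 correlated p-values is not a p-value: under the null
it is strongly anti-conservative (in our null simulations the uncorrected
in-range minimum p is below 0.05 in roughly a third of cohorts). `cutscan`
implements the scan together with the certification machinery that makes
its output honest.

## The scan

Let x₁…xₙ be the trait values and r(i) their zero-based ascending ranks
(stable in input order under ties). For each integer percentile c in the
scan range (default 1–99), the low group is the ⌊c·n/100⌋ lowest-ranked
samples and the high group the rest. Each split is scored with one of two
optimization tests:

* **Cox mode** — a proportional-hazards model with the single binary
  covariate z = 1(high): h(t|z) = h₀(t)·exp(βz). We report the Wald
  p-value from the observed information at the partial-likelihood MLE,
  with Efron's tie correction, and HR = exp(β) oriented so HR > 1 means
  the high group fares worse. A likelihood-ratio p is available
  (`BinaryCoxResult.p_lrt`). Splits with an empty group, a cohort with no
  events, or a monotone partial likelihood (complete separation of event
  order by group ⇒ infinite MLE) are recorded as invalid with a reason
  code — never silently dropped or given a fake p.
* **Fisher mode** — the two-sided exact test of the 2×2 table formed by
  the split against a fixed binary reference status, with the classical
  two-sided rule (sum of hypergeometric probabilities ≤ the observed
  table's). The reported odds ratio is the sample cross-product ratio
  with a Haldane–Anscombe 0.5 correction for zero cells.

The **optimal cut-off** is the in-range valid split with minimum p
(survival mode restricts the search to 10–90% so that neither subgroup is
vanishingly small; Fisher mode searches the full 1–99% by default). Ties
break toward the 50% split, then toward the lower percent, and are
flagged. If the global 1–99% minimum lies outside the search range, the
in-range ("secondary") optimum is returned with a flag. Because splits are
defined on ranks, every p-value in the scan is bit-identical under any
strictly monotone transformation of the trait — a property the test suite
asserts literally.

### Implementation note: the vectorized Cox engine

Certification re-runs the scan hundreds to thousands of times, so the
binary-covariate Cox fit is implemented directly (`cutscan/_cox.py`)
rather than through a general-purpose fitter. For a 0/1 covariate the
Efron partial likelihood at a tied event time depends only on four counts
(risk-set size, high-group members in the risk set, deaths, high-group
deaths), all obtainable from cumulative sums over the time-sorted cohort.
The Newton iteration therefore runs on *all* splits of a scan
simultaneously as (event-row × split) array arithmetic; a full 99-split
scan of a 300-patient cohort takes ~4 ms, and B = 1000 permutations a few
seconds. The fit agrees with a loop-based grid maximization of the Efron
likelihood to ~1e-7 and with lifelines to its convergence tolerance; the
tests keep both cross-checks.

## Certification

* **Subsample stability** — the scan is repeated on `n_resamples = 100`
  subsamples of `fraction = 0.70` of patients drawn without replacement;
  the distribution of per-subsample optimal percentiles shows whether the
  optimum is a property of the population or of a few patients.
* **Recurring cut-point clusters** — the resampled optima are sorted and
  merged while consecutive values are within `merge_gap = 5` percentile
  points; clusters holding ≥ `recurrence_frac = 20%` of the non-missing
  optima are *recurring*, and the number of distinct subgroups is
  recurring + 1 (two recurring clusters ⇒ low/inter/high stratification).
  No recurring cluster ⇒ the cut-off is flagged non-robust. The merge gap
  and recurrence fraction are configurable; the defaults separate a
  single-mode profile from a two-mode profile while labelling a flat
  profile non-robust, and were fixed before any acceptance measurement.
* **Permutation FDR** — trait values are randomly re-paired with the
  fixed outcome rows B times (default 1000) and the whole scan recomputed.
  With observed optimum (c\*, p\*): `fdr_ac` = #{b : p_b(c\*) ≤ p\*}/B asks
  whether *this* split's p is better than chance at the same split;
  `fdr_range` = #{b : min in-range p_b ≤ p\*}/B is a min-p
  (multiplicity-honest) empirical p-value for the whole search range.
  Both are floored at 1/B, the resolution of the permutation estimate.
* **Distribution outliers** — with center m = mean(x) and
  MAD = mean|x − m|, samples with |x − m| > 2·MAD are flagged and the
  percent rank of the smallest flagged value above the center is drawn on
  the resampled scan plot, so the user can see whether the optimal cut
  merely tracks a handful of extreme expressers. (A median-centered
  variant is available; "MAD" here is the *mean*, not median, absolute
  deviation.)

## Applying a certified cut

`assign_subgroups` applies one or two percentile cut-points with the same
floor-rank arithmetic as the scan, yielding low/(inter)/high labels;
`survival_summary` computes Kaplan–Meier product-limit curves per group
and hazard ratios of each non-low group against the low group from one
Cox model with indicator covariates (not pairwise models). The clinical
workflow around a new biomarker is supported by `univariate_screen`
(Fisher's exact test for categorical covariates — chi-square with a flag
beyond 2 levels — and two-sided Wilcoxon rank-sum for continuous ones,
exact when the combined n ≤ 50 and tie-free) and
`multivariate_cox_backward_aic`, which screens covariates at univariate
Cox p < 0.05 (or takes an explicit candidate list, e.g. from the Fisher/
Wilcoxon screen) and then drops one covariate per step, always the one
whose removal lowers AIC most, until no removal lowers AIC; ties break on
covariate name, and the elimination trace is returned so the final AIC
can be asserted minimal.

## Genome-wide co-expression mode

`genome_scan` applies the Fisher-mode scan to every gene of a matrix
against one fixed binary status, recording each gene's optimal percentile
and optimal p; `filter_signature` keeps genes whose optimal cut falls in
a window around the status-defining cut (default 75 ± 15%) and sorts them
by optimal p — the co-expression signature. Benjamini–Hochberg q-values
over per-gene optimal p are attached as a convenience column only; the
ranking is by raw optimal p. Per-gene resampling/permutation
certification is deliberately *not* run genome-wide (B = 1000 × 20k genes
is prohibitive and unnecessary for screening); certify nominated
finalists individually instead. An optional gene list (e.g. DNA-binding
transcription factors) subsets the output.

## Synthetic cohorts

The generator (`cutscan/simulate.py`) encodes the data-generating picture
the scan assumes, so every stage is testable without external downloads:

* **Expression** — a two-component Gaussian mixture, 75% "low" / 25%
  "high" by default (means 5 and 8, common SD 1 on a log2-like scale),
  giving the right-skewed, minority-overexpressed distribution typical of
  a subgroup-defining gene.
* **Survival** — exponential event times with hazard λ = 0.1 below the
  planted rank quantile q (default 0.75) and λ·HR (default 2.5) above it;
  exponential censoring at rate 0.03 yields ~20% censoring under the
  defaults (administrative censoring is available). The exponential
  choice keeps the group-wise hazard ratio exact and closed-form.
* **Co-expression matrices** — a driver status (top 1 − q of the driver
  trait) plus signature genes whose own high-component membership agrees
  with the driver status with a specified concordance; remaining genes
  are independent mixture noise.

The planted cut is defined on ranks, matching the engine's splits. What
the generator does *not* emulate: RNA-seq count noise, batch effects,
platform differences, non-proportional hazards, or informative censoring.
Passing the synthetic suites therefore demonstrates correctness of the
statistics and calibration of the certification under the assumed model,
not robustness to those real-data complications.

## Verification summary (what the test suite computes)

* Fisher p equals exact rational hypergeometric enumeration on **all**
  2×2 tables with n ≤ 20; Cox Wald p/HR match a grid-maximized Efron
  partial likelihood to 1e-4 on small non-separated toys.
* Scan p-values are bit-identical under strictly monotone trait
  transforms; group sizes are monotone and conserved across the scan.
* Null calibration: on 200 association-free cohorts (n = 200, HR = 1,
  B = 200), the fraction with `fdr_range` ≤ 0.05 sits inside the binomial
  95% band around 0.05 while the uncorrected minimum-p "significant"
  fraction is several-fold larger — the pair of facts that motivates the
  tool.
* Planted-cut recovery: on 50 cohorts (n = 300, cut at the 75th
  percentile, HR = 2.5, ~20% censoring) the median cut-off error is ≤ 5
  percentile points, and certification (fdr_range ≤ 0.05, two subgroups)
  succeeds in ≥ 45/50; with a rarer subgroup (cut 85%, HR = 3) the
  optimal cut beats the median cut's p in ≥ 45/50.

Certification loops in tests and in `scripts/acceptance.py` use B = 200
permutations per cohort (FDR resolution 0.005 against the 0.05 threshold)
and the cohort sizes above; these are the package's chosen simulation
sizes and are stated here so results are reproducible exactly.

## Known limitations

* The minimum-p cut-off is biased toward overestimating the effect size at
  the chosen cut (winner's curse); `fdr_ac`/`fdr_range` certify the
  p-value, not the HR magnitude. Validate effect sizes on independent data.
* No analytical (maximally-selected-rank-statistic) correction is
  provided — multiplicity control is permutation-only, by design.
* Cox mode assumes proportional hazards within each split and provides no
  diagnostics for it; no time-dependent covariates, stratification, or
  competing risks.
* Percentile splits are rank-based: with heavy ties the split point within
  a tie block follows input order (a warning is emitted when ties straddle
  a cut), and value-based thresholds are deliberately not offered.
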