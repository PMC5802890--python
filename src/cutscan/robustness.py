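"""Certification of a cut-off scan: stability, recurrence, and FDR.

A minimum-p cut-off is only trustworthy if (a) it recurs when the cohort is
subsampled, and (b) it beats what the same scan produces on permuted data.
This module implements both checks:

* ``resample_scan`` — re-run the scan on 100 subsamples of 70% of patients
  drawn without replacement, collecting the optimal percentile of each.
* ``detect_cutpoint_clusters`` — merge the resampled optima into clusters of
  nearby percentiles; each recurring cluster marks a distinct subgroup
  boundary, so ``n_subgroups = recurring clusters + 1``.
* ``permutation_fdr`` — rescan after randomly re-pairing trait values with
  outcomes.  ``fdr_ac`` is the fraction of permutations whose p at the
  observed optimal percentile beats the observed p (chance of this split
  looking this good by luck); ``fdr_range`` is the fraction whose best
  in-range p beats the observed optimum — a min-p null that prices in the
  multiplicity of scanning the whole range.  Both are floored at 1/B.
* ``outlier_threshold`` — flags samples beyond twice the mean absolute
  deviation of the trait, and reports the percentile where the upper
  outlier boundary falls, for overlay on the resampled scan plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import BinaryTrait, CohortTrait, SurvivalOutcome
from .scan import CutoffScan, find_optimal, scan_cutoffs

__all__ = [
    "resample_scan",
    "detect_cutpoint_clusters",
    "permutation_fdr",
    "outlier_threshold",
    "ResampleProfile",
    "CutpointClusters",
    "PermutationFDR",
    "OutlierThreshold",
]


@dataclass(frozen=True)
class ResampleProfile:
    optimal_percents: np.ndarray   # NaN where a resample had no valid in-range cut
    n_resamples: int
    fraction: float
    seed: int
    search_range: tuple
    curves: tuple = ()             # optional per-resample (percents, p) pairs

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.optimal_percents).sum())


@dataclass(frozen=True)
class CutpointClusters:
    clusters: tuple          # (center_percent, member_count) sorted by center
    recurring: tuple         # subset with member_count >= threshold
    n_subgroups: int | None  # len(recurring) + 1, None when nothing recurs
    robust: bool

    @property
    def centers(self) -> list:
        return [c for c, _ in self.recurring]


@dataclass(frozen=True)
class PermutationFDR:
    fdr_ac: float
    fdr_range: float
    n_permutations: int
    seed: int
    observed_percent: int
    observed_p: float


@dataclass(frozen=True)
class OutlierThreshold:
    mad: float
    center: float
    flags: np.ndarray
    upper_percentile: float  # NaN when no upper outliers
    lower_percentile: float  # NaN when no lower outliers


def resample_scan(trait: CohortTrait, outcome, test_kind: str = "coxph",
                  search_range=(10, 90), scan_range=(1, 99),
                  n_resamples: int = 100, fraction: float = 0.70,
                  seed: int = 0, keep_curves: bool = False) -> ResampleProfile:
    """Optimal percentiles across subsamples drawn without replacement.

    Each resample keeps ``floor(fraction * n)`` patients and reruns the full
    scan; a resample with no valid in-range cut contributes NaN.  Fully
    reproducible from ``seed``.
    """
    n = trait.n
    m = int(np.floor(fraction * n))
    if m < 10:
        raise ValueError(f"subsample size {m} too small (need >= 10)")
    rng = np.random.default_rng(seed)
    optima = np.full(n_resamples, np.nan)
    curves = []
    for b in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        idx.sort()  # keep trait-input order within the subsample
        sub_scan = scan_cutoffs(trait.subset(idx), outcome.subset(idx),
                                test_kind=test_kind, scan_range=scan_range)
        try:
            optima[b] = find_optimal(sub_scan, search_range).percent
        except ValueError:
            pass  # no valid in-range cut in this draw
        if keep_curves:
            curves.append((sub_scan.percents, sub_scan.p_values))
    return ResampleProfile(optima, n_resamples, fraction, seed,
                           tuple(search_range), tuple(curves))


def detect_cutpoint_clusters(profile: ResampleProfile, merge_gap: int = 5,
                             recurrence_frac: float = 0.20) -> CutpointClusters:
    """Group resampled optima into clusters of nearby percentiles.

    Sorted optima are merged while consecutive values are within
    ``merge_gap`` percentile points; a cluster is *recurring* when it holds
    at least ``recurrence_frac`` of the non-missing optima.  The number of
    distinct subgroups is one more than the number of recurring clusters;
    with no recurring cluster the cut-off is flagged non-robust.
    """
    vals = np.sort(profile.optimal_percents[~np.isnan(profile.optimal_percents)])
    if vals.size == 0:
        raise ValueError("no non-missing resample optima")
    breaks = np.flatnonzero(np.diff(vals) > merge_gap)
    groups = np.split(vals, breaks + 1)
    clusters = tuple((float(np.median(g)), int(g.size)) for g in groups)
    thresh = recurrence_frac * vals.size
    recurring = tuple((c, m) for c, m in clusters if m >= thresh)
    if recurring:
        return CutpointClusters(clusters, recurring, len(recurring) + 1, True)
    return CutpointClusters(clusters, recurring, None, False)


def permutation_fdr(trait: CohortTrait, outcome, test_kind: str = "coxph",
                    search_range=(10, 90), scan_range=(1, 99),
                    n_permutations: int = 1000, seed: int = 0) -> PermutationFDR:
    """Permutation false-discovery estimates at, and around, the optimum.

    Trait values are randomly re-paired with the (fixed) outcome rows; the
    whole scan is recomputed per permutation.  With observed optimum
    ``(c*, p*)``: ``fdr_ac = #{b : p_b(c*) <= p*} / B`` and ``fdr_range =
    #{b : min in-range p_b <= p*} / B``, each floored at ``1/B``.
    """
    if n_permutations <= 0:
        raise ValueError("n_permutations must be positive")
    if n_permutations < 100:
        import warnings
        warnings.warn(f"B={n_permutations} gives FDR resolution coarser than 0.01",
                      stacklevel=2)
    observed = find_optimal(
        scan_cutoffs(trait, outcome, test_kind=test_kind, scan_range=scan_range),
        search_range)
    c_star, p_star = observed.percent, observed.p_value
    lo, hi = search_range
    rng = np.random.default_rng(seed)
    hit_ac = hit_range = 0
    for _ in range(n_permutations):
        perm = CohortTrait(trait.sample_ids, rng.permutation(trait.values), trait.name)
        s = scan_cutoffs(perm, outcome, test_kind=test_kind, scan_range=scan_range)
        rec = s.record_at(c_star)
        if rec is not None and rec.valid and rec.p_value <= p_star:
            hit_ac += 1
        in_range = [r.p_value for r in s.records if lo <= r.percent <= hi and r.valid]
        if in_range and min(in_range) <= p_star:
            hit_range += 1
    b = n_permutations
    return PermutationFDR(max(hit_ac, 1) / b, max(hit_range, 1) / b, b, seed,
                          c_star, p_star)


def outlier_threshold(trait: CohortTrait, k: float = 2.0,
                      robust_center: bool = False) -> OutlierThreshold:
    """Flag distribution outliers beyond ``k`` mean absolute deviations.

    The center is the mean (or median with ``robust_center``); MAD is the
    mean of |x - center|.  The upper (lower) percentile is the percent rank
    of the smallest flagged value above (largest below) the center — the
    red line overlaid on the resampled scan plot.  A constant trait has
    MAD 0 and no outliers.
    """
    x = trait.values
    center = float(np.median(x) if robust_center else np.mean(x))
    mad = float(np.mean(np.abs(x - center)))
    if mad == 0:
        return OutlierThreshold(0.0, center, np.zeros(x.size, dtype=bool),
                                np.nan, np.nan)
    flags = np.abs(x - center) > k * mad
    upper = lower = np.nan
    hi_vals = x[flags & (x > center)]
    if hi_vals.size:
        boundary = hi_vals.min()
        upper = 100.0 * (x < boundary).sum() / x.size
    lo_vals = x[flags & (x < center)]
    if lo_vals.size:
        boundary = lo_vals.max()
        lower = 100.0 * (x <= boundary).sum() / x.size
    return OutlierThreshold(mad, center, flags, float(upper), float(lower))
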