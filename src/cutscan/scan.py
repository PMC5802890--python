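"""Percentile cut-off scanning: the minimum-p dichotomization engine.

The cohort is sorted by the continuous trait and split at every integer
percentile in the scan range; at each split the low and high groups are
compared with the chosen optimization test (Cox proportional hazards on a
survival outcome, or Fisher's exact test against a fixed binary reference).
The split minimizing the test p-value inside a restricted search range is
the optimal cut-off.  Splits are defined on ranks — the lowest
``floor(percent * n / 100)`` samples form the low group — so every result
depends on the trait only through its ranks and is invariant under strictly
monotone transformations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._cox import CoxStructure, fit_binary_cox
from .cohort import BinaryTrait, CohortTrait, SurvivalOutcome

__all__ = [
    "dichotomize",
    "coxph_test",
    "fisher_test",
    "scan_cutoffs",
    "find_optimal",
    "CutoffRecord",
    "CutoffScan",
    "OptimalCutoff",
]


def n_low_at(n: int, percent: int) -> int:
    """Size of the low group when splitting ``n`` samples at ``percent``%."""
    return int(np.floor(percent * n / 100.0))


def dichotomize(trait: CohortTrait, percent: int) -> BinaryTrait:
    """Split a cohort at one percentile: lowest-ranked samples get label 0.

    Raises for a percent outside [1, 99] or a split leaving a group empty
    (the scan itself records such splits as invalid instead of raising).
    """
    if not 1 <= percent <= 99:
        raise ValueError(f"percent must be in [1, 99], got {percent}")
    n = trait.n
    n_low = n_low_at(n, percent)
    if n_low == 0 or n_low == n:
        raise ValueError(f"cut at {percent}% leaves an empty group (n={n})")
    ranks = trait.ranks()
    if _ties_straddle(trait.values, ranks, n_low):
        warnings.warn(
            f"tied trait values straddle the {percent}% cut; "
            "split resolved by input order", stacklevel=2)
    return BinaryTrait(trait.sample_ids, (ranks >= n_low).astype(np.int8),
                       name=f"{trait.name}@{percent}%")


def _ties_straddle(values: np.ndarray, ranks: np.ndarray, n_low: int) -> bool:
    order = np.argsort(ranks)
    return bool(values[order[n_low - 1]] == values[order[n_low]])


def coxph_test(label: BinaryTrait, outcome: SurvivalOutcome):
    """Cox PH fit of a single high-vs-low indicator; returns (p, HR, (lo, hi)).

    Wald p-value with Efron tie handling; HR > 1 means the high (label 1)
    group has the worse survival.  Raises when the fit is undefined (empty
    group, no events, monotone likelihood).
    """
    structure = CoxStructure(outcome.time, outcome.event)
    res = fit_binary_cox(structure, label.group[:, None])
    if not res.valid[0]:
        raise ValueError(f"Cox fit undefined: {res.reason[0]}")
    return float(res.p_value[0]), float(res.hr[0]), (float(res.ci_low[0]), float(res.ci_high[0]))


def fisher_test(label: BinaryTrait, reference: BinaryTrait):
    """Two-sided Fisher's exact test of a 2x2 label-vs-reference table.

    Returns ``(p, odds_ratio)`` with the classical two-sided rule (sum of
    hypergeometric probabilities no larger than the observed table's).  The
    odds ratio is the sample cross-product ratio, with a Haldane–Anscombe
    0.5 correction when any cell is zero.  Raises if a margin is zero.
    """
    a = int(((label.group == 0) & (reference.group == 1)).sum())
    b = int(((label.group == 0) & (reference.group == 0)).sum())
    c = int(((label.group == 1) & (reference.group == 1)).sum())
    d = int(((label.group == 1) & (reference.group == 0)).sum())
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table: a margin is zero")
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return p, _sample_odds_ratio(a, b, c, d)


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


@dataclass(frozen=True)
class CutoffRecord:
    percent: int
    n_low: int
    n_high: int
    p_value: float        # NaN when invalid
    effect: float         # HR (Cox) or OR (Fisher); NaN when invalid
    ci_low: float = np.nan
    ci_high: float = np.nan
    valid: bool = True
    reason: str = ""


@dataclass(frozen=True)
class CutoffScan:
    """One record per scanned percentile."""

    records: tuple
    test_kind: str
    n: int
    trait_name: str = "trait"

    def __post_init__(self):
        pct = [r.percent for r in self.records]
        if any(b <= a for a, b in zip(pct, pct[1:])):
            raise ValueError("scan percents must be strictly increasing")

    @property
    def percents(self) -> np.ndarray:
        return np.array([r.percent for r in self.records])

    @property
    def p_values(self) -> np.ndarray:
        return np.array([r.p_value for r in self.records])

    def record_at(self, percent: int) -> CutoffRecord | None:
        for r in self.records:
            if r.percent == percent:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "percent": [r.percent for r in self.records],
                "n_low": [r.n_low for r in self.records],
                "n_high": [r.n_high for r in self.records],
                "p_value": [r.p_value for r in self.records],
                "effect": [r.effect for r in self.records],
                "effect_ci_low": [r.ci_low for r in self.records],
                "effect_ci_high": [r.ci_high for r in self.records],
                "valid": [r.valid for r in self.records],
                "reason": [r.reason for r in self.records],
            }
        )


@dataclass(frozen=True)
class OptimalCutoff:
    percent: int
    p_value: float
    effect: float
    ci_low: float
    ci_high: float
    median_p: float          # p at the 50% split, NaN if that split is invalid
    search_range: tuple
    flags: tuple = field(default=())


def scan_cutoffs(trait: CohortTrait, outcome, test_kind: str = "coxph",
                 scan_range=(1, 99)) -> CutoffScan:
    """Evaluate the optimization test at every integer percentile in range.

    ``outcome`` is a ``SurvivalOutcome`` for ``test_kind='coxph'`` or a
    ``BinaryTrait`` reference for ``test_kind='fisher'``.  Inputs must
    already be aligned (same samples, same order).  Invalid splits are
    flagged with a reason, never dropped.
    """
    lo, hi = int(scan_range[0]), int(scan_range[1])
    if not (1 <= lo <= hi <= 99):
        raise ValueError(f"scan_range must satisfy 1 <= lo <= hi <= 99, got {scan_range}")
    if len(trait) != len(outcome) or not np.array_equal(trait.sample_ids, outcome.sample_ids):
        raise ValueError("trait and outcome must be aligned (same samples, same order)")
    n = trait.n
    percents = np.arange(lo, hi + 1)
    nlow = np.floor(percents * n / 100.0).astype(int)
    ranks = trait.ranks()

    if test_kind == "coxph":
        if not isinstance(outcome, SurvivalOutcome):
            raise TypeError("coxph scan requires a SurvivalOutcome")
        records = _scan_cox(trait, outcome, percents, nlow, ranks)
    elif test_kind == "fisher":
        if not isinstance(outcome, BinaryTrait):
            raise TypeError("fisher scan requires a BinaryTrait reference (grouping data required)")
        records = _scan_fisher(outcome, percents, nlow, ranks, n)
    else:
        raise ValueError(f"unknown test_kind {test_kind!r}")
    return CutoffScan(tuple(records), test_kind, n, trait.name)


def _scan_cox(trait, outcome, percents, nlow, ranks):
    n = trait.n
    structure = CoxStructure(outcome.time, outcome.event)
    high = ranks[:, None] >= nlow[None, :]
    res = fit_binary_cox(structure, high)
    records = []
    for k, pct in enumerate(percents):
        records.append(CutoffRecord(
            percent=int(pct), n_low=int(nlow[k]), n_high=int(n - nlow[k]),
            p_value=float(res.p_value[k]), effect=float(res.hr[k]),
            ci_low=float(res.ci_low[k]), ci_high=float(res.ci_high[k]),
            valid=bool(res.valid[k]), reason=res.reason[k]))
    return records


def _scan_fisher(reference, percents, nlow, ranks, n):
    ref = reference.group
    k1 = int(ref.sum())
    if k1 == 0 or k1 == n:
        return [CutoffRecord(int(p), int(m), int(n - m), np.nan, np.nan,
                             valid=False, reason="reference has one class")
                for p, m in zip(percents, nlow)]
    order = np.argsort(ranks)
    ref_sorted = ref[order]
    cum_ref = np.concatenate([[0], np.cumsum(ref_sorted)])
    records = []
    for pct, m in zip(percents, nlow):
        m = int(m)
        if m == 0 or m == n:
            records.append(CutoffRecord(int(pct), m, n - m, np.nan, np.nan,
                                        valid=False, reason="empty group"))
            continue
        a = int(cum_ref[m])          # low & ref=1
        b = m - a                    # low & ref=0
        c = k1 - a                   # high & ref=1
        d = (n - m) - c              # high & ref=0
        p = float(stats.fisher_exact([[a, b], [c, d]])[1])
        records.append(CutoffRecord(int(pct), m, n - m, p,
                                    _sample_odds_ratio(a, b, c, d)))
    return records


def find_optimal(scan: CutoffScan, search_range=(10, 90)) -> OptimalCutoff:
    """Locate the minimum-p split within the search range.

    Ties on p are broken toward the 50% split, then toward the lower
    percent; ties and out-of-range global optima are flagged.  When the
    1–99% global optimum falls outside the range, the best in-range split
    (the "secondary" optimum) is returned with a flag.  Raises when no
    in-range split is valid.
    """
    lo, hi = int(search_range[0]), int(search_range[1])
    in_range = [r for r in scan.records if lo <= r.percent <= hi and r.valid]
    if not in_range:
        raise ValueError(f"no valid cut-off in search range [{lo}, {hi}]")
    pmin = min(r.p_value for r in in_range)
    ties = [r for r in in_range if r.p_value == pmin]
    best = min(ties, key=lambda r: (abs(r.percent - 50), r.percent))
    flags = []
    if len(ties) > 1:
        flags.append("tie")
    all_valid = [r for r in scan.records if r.valid]
    gbest = min(all_valid, key=lambda r: (r.p_value, abs(r.percent - 50), r.percent))
    if not (lo <= gbest.percent <= hi) and gbest.p_value < pmin:
        flags.append("secondary optimal cutoff used")
    med = scan.record_at(50)
    median_p = med.p_value if (med is not None and med.valid) else np.nan
    return OptimalCutoff(best.percent, best.p_value, best.effect, best.ci_low,
                         best.ci_high, median_p, (lo, hi), tuple(flags))
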