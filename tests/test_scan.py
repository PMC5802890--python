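"""Scan engine: dichotomization arithmetic, scanning, optimum selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cutscan import (CohortTrait, SurvivalOutcome, dichotomize, find_optimal,
                     scan_cutoffs)
from cutscan.scan import CutoffRecord, CutoffScan, n_low_at

from conftest import ids, make_binary, make_outcome, make_trait


class TestDichotomize:
    def test_exact_halves(self, toy_trait):
        lab = dichotomize(toy_trait, 50)
        assert lab.group.sum() == 5
        assert lab.group.tolist() == [0] * 5 + [1] * 5

    @pytest.mark.parametrize("n,percent,n_low", [
        (161, 76, 122),   # floor(0.76 * 161)
        (10, 50, 5),
        (100, 75, 75),
        (7, 99, 6),
    ])
    def test_floor_arithmetic(self, n, percent, n_low):
        assert n_low_at(n, percent) == n_low

    def test_degenerate_cut_raises_outside_scan(self):
        with pytest.raises(ValueError, match="empty group"):
            dichotomize(make_trait(np.arange(10.0)), 5)  # floor(0.05*10) = 0

    def test_percent_out_of_bounds(self, toy_trait):
        with pytest.raises(ValueError):
            dichotomize(toy_trait, 0)
        with pytest.raises(ValueError):
            dichotomize(toy_trait, 100)

    def test_tie_straddle_warns(self):
        t = make_trait([1.0, 2.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="tied"):
            dichotomize(t, 50)

    @given(st.integers(3, 60), st.integers(1, 99))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_group_sizes_partition_cohort(self, n, percent):
        t = make_trait(np.arange(float(n)))
        n_low = n_low_at(n, percent)
        if n_low in (0, n):
            return
        lab = dichotomize(t, percent)
        assert (lab.group == 0).sum() == n_low
        assert (lab.group == 1).sum() == n - n_low


class TestScan:
    def test_full_range_gives_99_records(self, planted_cohort):
        trait, outcome = planted_cohort
        scan = scan_cutoffs(trait, outcome)
        assert len(scan.records) == 99
        assert scan.percents.tolist() == list(range(1, 100))

    def test_rank_invariance_bit_identical(self, planted_cohort):
        trait, outcome = planted_cohort
        base = scan_cutoffs(trait, outcome).p_values
        for f in (np.exp, lambda x: x**3, lambda x: 2.0 * x + 1.0):
            warped = CohortTrait(trait.sample_ids, f(trait.values), trait.name)
            np.testing.assert_array_equal(scan_cutoffs(warped, outcome).p_values, base)

    def test_group_sizes_monotone_and_conserved(self, planted_cohort):
        trait, outcome = planted_cohort
        scan = scan_cutoffs(trait, outcome)
        n_low = np.array([r.n_low for r in scan.records])
        assert (np.diff(n_low) >= 0).all()
        assert all(r.n_low + r.n_high == trait.n for r in scan.records)

    def test_invalid_cuts_flagged_not_dropped(self):
        t = make_trait(np.arange(10.0))
        o = make_outcome(np.arange(1.0, 11.0), np.ones(10, int))
        scan = scan_cutoffs(t, o, scan_range=(1, 99))
        r5 = scan.record_at(5)      # n_low = 0
        assert not r5.valid and r5.reason == "empty group"
        assert len(scan.records) == 99

    def test_misaligned_inputs_rejected(self, toy_trait):
        o = make_outcome(np.arange(1.0, 11.0), np.ones(10, int))
        other = SurvivalOutcome(ids(10, "X"), o.time, o.event)
        with pytest.raises(ValueError, match="aligned"):
            scan_cutoffs(toy_trait, other)

    def test_fisher_requires_binary_reference(self, toy_trait, toy_outcome):
        with pytest.raises(TypeError, match="grouping data required"):
            scan_cutoffs(toy_trait, toy_outcome, test_kind="fisher")

    def test_constant_trait_deterministic_fisher(self):
        # ties split by input order; scanning twice gives identical tables
        t = make_trait(np.zeros(12))
        ref = make_binary([0, 1] * 6)
        s1 = scan_cutoffs(t, ref, test_kind="fisher")
        s2 = scan_cutoffs(t, ref, test_kind="fisher")
        np.testing.assert_array_equal(s1.p_values, s2.p_values)


def _scan_from(pairs, n=100, test_kind="coxph", full=False):
    """Build a CutoffScan from (percent, p) pairs; other fields are dummies."""
    recs = [CutoffRecord(p, n_low_at(n, p), n - n_low_at(n, p), pv, 1.0)
            for p, pv in pairs]
    return CutoffScan(tuple(recs), test_kind, n)


class TestFindOptimal:
    def test_argmin(self):
        scan = _scan_from([(40, 0.5), (50, 0.01), (60, 0.2)])
        best = find_optimal(scan)
        assert best.percent == 50
        assert best.p_value == 0.01
        assert best.median_p == 0.01

    def test_tie_broken_toward_50_then_lower(self):
        best = find_optimal(_scan_from([(30, 0.01), (50, 0.5), (70, 0.01)]))
        assert best.percent == 30          # equidistant from 50 -> lower percent
        assert "tie" in best.flags
        best2 = find_optimal(_scan_from([(30, 0.01), (45, 0.01), (50, 0.5)]))
        assert best2.percent == 45         # closer to 50 wins

    def test_secondary_optimum_flagged(self):
        scan = _scan_from([(50, 0.3), (69, 1e-3), (95, 1e-6)])
        best = find_optimal(scan, search_range=(10, 90))
        assert best.percent == 69
        assert "secondary optimal cutoff used" in best.flags

    def test_no_valid_record_in_range(self):
        scan = _scan_from([(95, 1e-6)])
        with pytest.raises(ValueError, match="no valid cut-off"):
            find_optimal(scan, search_range=(10, 90))

    def test_median_p_nan_when_50_not_scanned(self):
        best = find_optimal(_scan_from([(40, 0.2), (60, 0.1)]))
        assert np.isnan(best.median_p)
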