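"""Tests of HDR construction and the fragility index pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltfu_fragility import (
    ArmObservation,
    JointPredictive,
    TrialTable,
    hdr,
    impute_modes,
    ltfu_fragility_index,
    max_reversal_q,
    minimal_coverage,
    reversal_probability,
    significance_grid,
)


def random_joint(rng, shape=(5, 6)):
    mass = rng.random(shape)
    return JointPredictive(mass / mass.sum())


class TestHDR:
    def test_q_zero_full_support(self, excel_joint):
        region = hdr(excel_joint, 0.0)
        assert len(region.cells) == 65 * 96
        assert region.attained_coverage == pytest.approx(1.0, abs=1e-9)

    def test_q_one_is_mode_set(self, excel_joint):
        region = hdr(excel_joint, 1.0)
        assert region.cells == [(14, 19)]

    def test_invalid_q(self, gold_joint):
        with pytest.raises(ValueError):
            hdr(gold_joint, -0.1)
        with pytest.raises(ValueError):
            hdr(gold_joint, 1.5)

    def test_nesting_and_mode_membership(self, rng):
        """HDRs are nested in q and always contain every mode."""
        for _ in range(20):
            joint = random_joint(rng)
            modes = set(impute_modes(joint))
            previous = None
            for q in [0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0]:
                cells = set(hdr(joint, q).cells)
                assert modes <= cells
                if previous is not None:
                    assert cells <= previous
                previous = cells

    def test_coverage_meets_nominal(self, rng):
        for _ in range(10):
            joint = random_joint(rng, shape=(4, 7))
            for q in [0.05, 0.25, 0.6]:
                region = hdr(joint, q)
                assert region.attained_coverage >= 1.0 - q - 1e-12

    def test_tied_mass_included_together(self):
        joint = JointPredictive(np.array([[0.4, 0.2], [0.2, 0.2]]))
        region = hdr(joint, 0.5)
        # 0.4 alone reaches 1-q=0.5 only with one of the tied 0.2 cells,
        # and all three tied cells must enter together
        assert len(region.cells) == 4


class TestMaxReversalQ:
    def test_excel_smallest_reversing_region(self, excel_joint, excel_grid):
        """The smallest credible region containing a reversing outcome:
        the published threshold is 0.251, reproduced within 0.005 by
        exact quadrature."""
        q = max_reversal_q(excel_joint, excel_grid)
        assert q == pytest.approx(0.251, abs=0.005)

    def test_boundary_is_sharp(self, excel_joint, excel_grid):
        """hdr(q) contains a reversing cell for all q up to the returned
        value, and none once q also exceeds the boundary cell's own mass
        (the cell stays needed until the cumulative target drops past it)."""
        q = max_reversal_q(excel_joint, excel_grid)
        rev = excel_grid.reverses
        inside = [cell for cell in hdr(excel_joint, q).cells if rev[cell]]
        assert inside
        boundary_mass = max(excel_joint.mass[cell] for cell in inside)
        above = [
            cell
            for cell in hdr(excel_joint, q + boundary_mass + 1e-9).cells
            if rev[cell]
        ]
        assert not above

    def test_gopcabe_none(self, gopcabe_joint, gopcabe_grid):
        assert max_reversal_q(gopcabe_joint, gopcabe_grid) is None

    def test_mode_reversal_brute_force(self, gold_joint, gold_grid):
        """When the mode itself reverses, the value matches a direct
        sorted-mass summation."""
        assert gold_grid.reverses[7, 6]
        q = max_reversal_q(gold_joint, gold_grid)
        flat = np.sort(gold_joint.mass.ravel())[::-1]
        mode_mass = gold_joint.mass[7, 6]
        expected = 1.0 - flat[flat >= mode_mass * (1 - 1e-12)].sum()
        assert q == pytest.approx(expected, abs=1e-12)


class TestReversalProbability:
    def test_gopcabe_zero(self, gopcabe_joint, gopcabe_grid):
        assert reversal_probability(gopcabe_joint, gopcabe_grid) == 0.0

    def test_all_reversing_sums_to_one(self, gold_joint, gold_grid):
        from dataclasses import replace

        everywhere = replace(
            gold_grid, significant=np.ones(gold_grid.shape, dtype=bool)
        )
        assert reversal_probability(gold_joint, everywhere) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_small_trial_brute_force(self):
        """Matches exhaustive cell-by-cell summation on a 4x4 grid."""
        trial = TrialTable(ArmObservation(6, 4, 3), ArmObservation(2, 8, 3))
        grid = significance_grid(trial, alpha=0.05)
        from ltfu_fragility import joint_predictive, posterior_predictive_pmf, solve_s

        s_c, s_t = solve_s(trial.control.p_hat), solve_s(trial.treatment.p_hat)
        joint = joint_predictive(
            posterior_predictive_pmf(trial.control, s_c),
            posterior_predictive_pmf(trial.treatment, s_t),
        )
        expected = sum(
            joint.mass[r, c]
            for r in range(4)
            for c in range(4)
            if grid.significant[r, c] != grid.baseline_significant
        )
        assert reversal_probability(joint, grid) == pytest.approx(expected, abs=1e-12)


class TestMinimalCoverage:
    def test_mode_has_smallest_coverage(self, gold_joint):
        mode_mass = gold_joint.mass[7, 6]
        assert minimal_coverage(gold_joint, (7, 6)) == pytest.approx(
            mode_mass, abs=1e-12
        )

    def test_gold_known_outcome_coverage(self, gold_joint):
        """The realised (2,2) lost outcomes are so unusual that only a
        ~95.5% credible region includes them."""
        assert minimal_coverage(gold_joint, (2, 2)) == pytest.approx(0.955, abs=0.005)

    def test_consistent_with_sorted_mass_oracle(self, gold_joint, rng):
        flat = gold_joint.mass.ravel()
        for _ in range(20):
            r = int(rng.integers(0, 24))
            c = int(rng.integers(0, 34))
            expected = flat[flat >= gold_joint.mass[r, c] * (1 - 1e-12)].sum()
            assert minimal_coverage(gold_joint, (r, c)) == pytest.approx(
                expected, abs=1e-15
            )

    def test_out_of_range(self, gold_joint):
        with pytest.raises(ValueError):
            minimal_coverage(gold_joint, (24, 0))


class TestFragilityIndex:
    def test_excel_q_zero(self, excel):
        """Unconstrained search: 12 modified lost outcomes reverse EXCEL."""
        report = ltfu_fragility_index(excel, q=0.0)
        assert report.fi == 12
        assert report.modes == [(14, 19)]
        assert not report.baseline_significant

    def test_excel_at_smallest_reversing_region(self, excel):
        """At the boundary threshold (published as q = 0.251) one more
        modification is needed: 13."""
        probe = ltfu_fragility_index(excel, q=0.0)
        report = ltfu_fragility_index(excel, q=probe.max_reversal_q)
        assert report.fi == 13

    @pytest.mark.parametrize("q", [0.0, 0.5, 0.9])
    def test_gold_zero_for_any_q(self, gold, q):
        """Gold's imputed expected outcomes already reverse significance,
        so the index is 0 at every threshold with a nonempty region."""
        report = ltfu_fragility_index(gold, q=q)
        assert report.fi == 0
        assert report.modes == [(7, 6)]
        assert report.imputed_p_value == pytest.approx(0.041, abs=5e-4)
        assert report.achieving_cells == [(7, 6)]

    @pytest.mark.parametrize("q", [0.0, 0.5])
    def test_gopcabe_infinite(self, gopcabe, q):
        report = ltfu_fragility_index(gopcabe, q=q)
        assert math.isinf(report.fi)
        assert report.infinite
        assert report.reversal_probability == 0.0
        assert report.max_reversal_q is None
        assert report.per_mode_minima == []

    def test_fi_zero_iff_mode_reverses(self, gold, gopcabe):
        assert ltfu_fragility_index(gold, q=0.0).fi == 0
        assert ltfu_fragility_index(gopcabe, q=0.0).fi != 0

    def test_monotone_in_q(self, excel, excel_joint, excel_grid):
        """The index never decreases as rarer outcomes are excluded."""
        rev = excel_grid.reverses
        mode = (14, 19)
        values = []
        for q in [0.0, 0.05, 0.1, 0.15, 0.2, 0.24]:
            cells = [cell for cell in hdr(excel_joint, q).cells if rev[cell]]
            assert cells
            fi = min(abs(r - mode[0]) + abs(c - mode[1]) for r, c in cells)
            values.append(fi)
        assert values == sorted(values)
        assert values[0] == 12

    def test_q_zero_equals_unconstrained_minimum(self, excel, excel_joint, excel_grid):
        """fi(q=0) matches a brute-force scan of the full grid."""
        rev = excel_grid.reverses
        brute = min(
            abs(r - 14) + abs(c - 19)
            for r in range(65)
            for c in range(96)
            if rev[r, c]
        )
        assert ltfu_fragility_index(excel, q=0.0).fi == brute

    def test_multi_mode_median_rule(self):
        """With tied modes the search runs from each mode and the median
        of the per-mode minima is reported (half-integer permitted)."""
        from ltfu_fragility import PriorSettings

        # s = 0 makes both predictives uniform, so every cell is a mode
        trial = TrialTable(ArmObservation(2, 8, 4), ArmObservation(8, 2, 3))
        report = ltfu_fragility_index(
            trial, q=0.0, settings=PriorSettings(s_control=0.0, s_treatment=0.0)
        )
        assert report.baseline_significant  # 2/10 vs 8/10 events
        assert len(report.modes) == 5 * 4
        assert len(report.per_mode_minima) == len(report.modes)
        assert not math.isinf(report.fi)
        assert report.fi == pytest.approx(float(np.median(report.per_mode_minima)))

    def test_fi_bounded_by_total_ltfu(self, gold):
        report = ltfu_fragility_index(gold, q=0.0)
        assert report.fi <= gold.control.n_lost + gold.treatment.n_lost
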