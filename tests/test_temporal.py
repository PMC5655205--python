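import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbncs.info_theory import gaussian_mi
from dbncs.io_formats import ExpressionMatrix
from dbncs.structure_learning import Skeleton
from dbncs.temporal import (
    DegenerateTargetError,
    DelayMatrix,
    TRSInput,
    build_delay_matrix,
    optimal_delay,
    recombine,
    trs,
)

from .conftest import ar1_series


class TestRecombine:
    def test_lengths_after_shift(self):
        x = np.arange(5.0)
        a, b = recombine(x, x + 10, 2)
        assert len(a) == len(b) == 3

    def test_alignment_content(self):
        a, b = recombine(np.array([1.0, 2, 3]), np.array([7.0, 8, 9]), 1)
        np.testing.assert_array_equal(a, [1, 2])
        np.testing.assert_array_equal(b, [8, 9])

    def test_shift_too_large_is_error(self):
        with pytest.raises(ValueError):
            recombine(np.arange(4.0), np.arange(4.0), 3)

    def test_mi_of_recombined_equals_direct_definition(self, rng):
        x, y = rng.standard_normal((2, 30))
        m = 3
        assert gaussian_mi(*recombine(x, y, m)) == gaussian_mi(x[:-m], y[m:])


class TestOptimalDelay:
    def test_planted_shift_recovered(self):
        r = np.random.default_rng(7)
        x = ar1_series(r, 50)
        y = np.r_[np.zeros(2), x[:-2]] + 0.01 * r.standard_normal(50)
        m, mi = optimal_delay(x, y, 5)
        assert m == 2 and mi > 1.0

    def test_single_candidate_always_chosen(self, rng):
        x, y = rng.standard_normal((2, 20))
        assert optimal_delay(x, y, 1)[0] == 1

    def test_affine_invariance(self):
        r = np.random.default_rng(11)
        x = ar1_series(r, 40)
        y = np.r_[0, x[:-1]] + 0.05 * r.standard_normal(40)
        assert optimal_delay(x, y, 4)[0] == optimal_delay(5 * x - 2, -3 * y + 1, 4)[0]

    def test_recovery_rate_on_planted_pairs(self):
        """Planted shifts in {1..5}, noise 10% of signal sd: >=90% recovered."""
        ok = 0
        for seed in range(50):
            r = np.random.default_rng(400 + seed)
            x = ar1_series(r, 55)
            s = 1 + seed % 5
            y = np.r_[np.zeros(s), x[:-s]] + 0.1 * np.std(x) * r.standard_normal(55)
            ok += optimal_delay(x[5:], y[5:], 5)[0] == s
        assert ok >= 45


class TestBuildDelayMatrix:
    def test_empty_skeleton_gives_zero_matrix(self, rng):
        expr = ExpressionMatrix(["A", "B"], rng.standard_normal((2, 20)))
        dm = build_delay_matrix(expr, Skeleton(["A", "B"], np.zeros((2, 2)), 0), 3)
        assert not dm.delays.any()

    def test_planted_directed_pair_fills_both_directions(self):
        r = np.random.default_rng(5)
        x = ar1_series(r, 60)
        y = np.r_[np.zeros(3), x[:-3]] + 0.05 * r.standard_normal(60)
        expr = ExpressionMatrix(["X", "Y"], np.vstack([x, y]))
        skel = Skeleton(["X", "Y"], np.array([[0, 1.0], [1.0, 0]]), 0)
        dm = build_delay_matrix(expr, skel, 5)
        assert dm.delays[0, 1] == 3
        assert 1 <= dm.delays[1, 0] <= 5

    def test_matrix_can_be_asymmetric(self):
        r = np.random.default_rng(5)
        x = ar1_series(r, 60)
        y = np.r_[np.zeros(3), x[:-3]] + 0.05 * r.standard_normal(60)
        expr = ExpressionMatrix(["X", "Y"], np.vstack([x, y]))
        skel = Skeleton(["X", "Y"], np.array([[0, 1.0], [1.0, 0]]), 0)
        dm = build_delay_matrix(expr, skel, 5)
        assert dm.delays[0, 1] != dm.delays[1, 0]

    def test_delay_matrix_invariants_enforced(self):
        with pytest.raises(ValueError):
            DelayMatrix(np.array([[1, 0], [0, 0]]), 3)  # non-zero diagonal
        with pytest.raises(ValueError):
            DelayMatrix(np.array([[0, 7], [0, 0]]), 3)  # above k_max


class TestTRS:
    def test_hand_computed_six_point_example(self):
        # x = [1,2,2,3,1,1], y = [0,1,3,2,2,4]:
        #   t=0: x changes, y step +2      -> +1 (counts)
        #   t=1: x flat,    y step -1      ->  0 (counts)
        #   t=2: x changes, y step  0      ->  skipped (no target change)
        #   t=3: x changes, y step +2      -> +1 (counts)
        # N_IC = 3, sum = 2, TRS = 1 - 2/3
        inp = TRSInput(np.array([1.0, 2, 2, 3, 1, 1]), np.array([0.0, 1, 3, 2, 2, 4]))
        assert trs(inp) == pytest.approx(1 - 2 / 3)

    def test_constant_regulator_gives_one(self):
        inp = TRSInput(np.ones(6), np.array([0.0, 1, 0, 2, 1, 3]))
        assert trs(inp) == pytest.approx(1.0)

    def test_constant_target_is_degenerate(self):
        with pytest.raises(DegenerateTargetError):
            trs(TRSInput(np.arange(6.0), np.ones(6)))

    def test_always_changing_regulator_monotone_target(self):
        # every summand is +1, so TRS = 1 - N_IC/N_IC = 0
        inp = TRSInput(np.array([1.0, 2, 1, 2, 1, 2]), np.arange(6.0))
        assert trs(inp) == pytest.approx(0.0)

    def test_anti_correlated_dynamics_can_exceed_one(self):
        inp = TRSInput(np.array([1.0, 2, 1, 2, 1, 2]), -np.arange(6.0))
        assert trs(inp) == pytest.approx(2.0)

    def test_change_eps_masks_small_fluctuations(self):
        x = np.array([0.0, 0.001, 0.002, 0.003, 0.004, 0.005])
        y = np.array([0.0, 1, 2, 3, 4, 5])
        assert trs(TRSInput(x, y), change_eps=0.01) == pytest.approx(1.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounded_between_zero_and_two(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(12)
        y = r.standard_normal(12)
        assert 0.0 <= trs(TRSInput(x, y)) <= 2.0
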