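"""Exact DTW against an exhaustive-enumeration oracle, plus the smooth
variant's convergence and gradient behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hveegnet.dtw import (SoftDtwConfig, dtw, dtw_cost_matrix, multichannel_dtw,
                          normalized_dtw_score, optimal_warping_path, soft_dtw,
                          soft_dtw_grad)

from conftest import brute_force_dtw

short_seq = st.lists(st.integers(min_value=-3, max_value=3), min_size=1, max_size=6)


class TestCostMatrix:
    def test_identical_series_zero_diagonal(self):
        W = dtw_cost_matrix([1, 2, 3], [1, 2, 3])
        assert np.allclose(np.diag(W), 0.0)
        assert W[-1, -1] == 0.0

    @pytest.mark.parametrize("a, b, corner", [
        ([0, 0], [1, 1], 2.0),            # enumeration oracle value
        ([1, 3], [1, 2, 3], 1.0),         # hand-executed recurrence
        ([5, 5, 5, 5], [5, 5, 5, 5], 0.0),
    ])
    def test_known_corner_costs(self, a, b, corner):
        assert dtw_cost_matrix(a, b)[-1, -1] == pytest.approx(corner)

    def test_recurrence_structure(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=7)
        W = dtw_cost_matrix(a, b)
        assert np.all(W >= 0)
        # every interior cell satisfies the stated recurrence
        local = np.abs(a[:, None] - b[None, :])
        for i in range(1, 5):
            for j in range(1, 7):
                assert W[i, j] == pytest.approx(
                    local[i, j] + min(W[i - 1, j - 1], W[i, j - 1], W[i - 1, j]))
        assert W[0, 0] == pytest.approx(local[0, 0])

    @pytest.mark.parametrize("a, b", [([], [1]), ([1], []),
                                      ([np.nan, 1], [1, 2]), ([1], [np.inf])])
    def test_invalid_inputs_rejected(self, a, b):
        with pytest.raises(ValueError):
            dtw_cost_matrix(a, b)

    def test_oracle_equivalence_random_pairs(self, rng):
        """Corner cost equals the exhaustive-path-enumeration minimum on
        >=1000 random integer pairs of length <= 6 (exact equality)."""
        for _ in range(1000):
            la, lb = rng.integers(1, 7, size=2)
            a = rng.integers(-3, 4, size=la).astype(float)
            b = rng.integers(-3, 4, size=lb).astype(float)
            assert dtw_cost_matrix(a, b)[-1, -1] == brute_force_dtw(a, b)


class TestWarpingPath:
    def test_identical_series_diagonal_path(self):
        W = dtw_cost_matrix([4, 5, 6], [4, 5, 6])
        path, d, K = optimal_warping_path(W)
        assert path == [(0, 0), (1, 1), (2, 2)]
        assert K == 3
        assert np.allclose(d, 0.0)

    def test_hand_executed_example(self):
        W = dtw_cost_matrix([0, 0], [1, 1])
        path, d, K = optimal_warping_path(W)
        assert path == [(0, 0), (1, 1)]
        assert list(d) == [1.0, 2.0]

    @given(a=short_seq, b=short_seq)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_path_validity(self, a, b):
        W = dtw_cost_matrix(a, b)
        path, d, K = optimal_warping_path(W)
        assert path[0] == (0, 0) and path[-1] == (len(a) - 1, len(b) - 1)
        assert K >= max(len(a), len(b)) and K == len(d)
        steps = {(p2[0] - p1[0], p2[1] - p1[1]) for p1, p2 in zip(path, path[1:])}
        assert steps <= {(1, 0), (0, 1), (1, 1)}
        # W is non-decreasing along the path (costs are non-negative)
        assert np.all(np.diff(d) >= -1e-12)

    def test_malformed_matrix_rejected(self):
        with pytest.raises(ValueError):
            optimal_warping_path(np.zeros((0, 0)))


class TestNormalizedScore:
    def test_identity_is_zero(self, rng):
        a = rng.normal(size=20)
        assert normalized_dtw_score(a, a) == 0.0

    def test_both_normalization_modes(self):
        # d = [1, 2], K = 2: path-mean 1.5; corner/K = 1.0
        assert normalized_dtw_score([0, 0], [1, 1], mode="path-mean") == 1.5
        assert normalized_dtw_score([0, 0], [1, 1], mode="corner") == 1.0
        res = dtw([0, 0], [1, 1])
        assert res.scores == {"path-mean": 1.5, "corner": 1.0}

    @given(a=short_seq, b=short_seq)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetry_and_nonnegativity(self, a, b):
        assert dtw(a, b).corner_cost == pytest.approx(dtw(b, a).corner_cost)
        assert normalized_dtw_score(a, b) >= 0


class TestSoftDtw:
    def test_underestimates_on_identical_series(self):
        assert soft_dtw([3, 3, 3], [3, 3, 3]) <= 1e-9

    def test_converges_to_exact_corner(self, rng):
        cfg = SoftDtwConfig(gamma=0.001)
        assert soft_dtw([0, 0], [1, 1], cfg) == pytest.approx(2.0, abs=0.05)
        for _ in range(20):
            a, b = rng.normal(size=8), rng.normal(size=8)
            assert soft_dtw(a, b, cfg) == pytest.approx(
                dtw(a, b).corner_cost, abs=0.05)

    def test_monotone_in_temperature(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert soft_dtw(a, b, SoftDtwConfig(gamma=1.0)) <= \
            soft_dtw(a, b, SoftDtwConfig(gamma=0.001))

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            SoftDtwConfig(gamma=0.0)

    def test_gradient_matches_finite_differences(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        cfg = SoftDtwConfig(gamma=0.5)
        _, grad = soft_dtw_grad(a, b, cfg)
        eps = 1e-6
        for i in range(12):
            e = np.zeros(12)
            e[i] = eps
            num = (soft_dtw(a + e, b, cfg) - soft_dtw(a - e, b, cfg)) / (2 * eps)
            assert grad[i] == pytest.approx(num, abs=1e-6)

    def test_band_limits_computation_but_matches_when_wide(self, rng):
        a, b = rng.normal(size=15), rng.normal(size=15)
        full = soft_dtw(a, b, SoftDtwConfig(gamma=0.1))
        banded = soft_dtw(a, b, SoftDtwConfig(gamma=0.1, bandwidth=15))
        assert banded == pytest.approx(full)


class TestMultichannel:
    def test_perfect_reconstruction_is_zero(self, rng):
        x = rng.normal(size=(3, 30))
        assert multichannel_dtw(x, x, mode="loss-sum") <= 1e-9
        assert np.allclose(multichannel_dtw(x, x, mode="eval-per-channel"), 0.0)

    def test_loss_sum_additivity_over_channels(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0]])
        y = np.array([[1.0, 1.0], [1.0, 1.0]])
        # each channel has exact corner cost 2; tight temperature ~ exact
        total = multichannel_dtw(x, y, mode="loss-sum", cfg=SoftDtwConfig(gamma=1e-4))
        assert total == pytest.approx(4.0, abs=0.01)

    def test_eval_mode_returns_per_channel_vector(self, rng):
        x, y = rng.normal(size=(5, 20)), rng.normal(size=(5, 20))
        v = multichannel_dtw(x, y, mode="eval-per-channel")
        assert v.shape == (5,)
        assert np.all(v >= 0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            multichannel_dtw(rng.normal(size=(2, 10)), rng.normal(size=(3, 10)))
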