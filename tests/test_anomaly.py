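"""Error-matrix construction, kNN + knee outlier detection and the
transition-point locator — on constructed matrices with known answers."""

import numpy as np
import pytest

from hveegnet.anomaly import (ErrorMatrix, average_error_matrices,
                              compute_error_matrix, detect_outliers,
                              find_transition_point, kneedle)
from hveegnet.dtw import multichannel_dtw
from hveegnet.models import build_model
from hveegnet.synthetic import generate_clean


class _IdentityModel:
    """Perfect reconstructor used to pin the all-zero error matrix."""

    def reconstruct(self, x):
        return np.asarray(x, dtype=float)

    def forward(self, x, seed=0, sample=True):
        return np.asarray(x, dtype=float)


class TestErrorMatrix:
    def test_identity_reconstructor_gives_zero_matrix(self, rng):
        data = rng.normal(size=(5, 1, 3, 20))
        E = compute_error_matrix(_IdentityModel(), data)
        assert E.values.shape == (5, 3)
        assert np.allclose(E.values, 0.0)

    def test_agrees_with_eval_per_channel_mode(self, tiny_arch, rng):
        model = build_model(tiny_arch, "hveegnet", seed=0)
        data = generate_clean(1, 3, 4, 128, 64.0, seed=1).segments(0)
        E = compute_error_matrix(model, data)
        rec = model.reconstruct(data)
        for r in range(3):
            expected = multichannel_dtw(data[r, 0], rec[r, 0],
                                        mode="eval-per-channel")
            assert np.allclose(E.values[r], expected)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            ErrorMatrix(values=np.array([[-1.0, 0.0]]))


class TestAveraging:
    def test_identical_matrices_average_to_themselves(self, rng):
        E = ErrorMatrix(rng.uniform(0, 2, size=(4, 3)))
        avg = average_error_matrices([E, E, E])
        assert np.allclose(avg.values, E.values)

    def test_elementwise_mean(self):
        a = ErrorMatrix(np.full((2, 2), 1.0))
        b = ErrorMatrix(np.full((2, 2), 3.0))
        assert np.allclose(average_error_matrices([a, b]).values, 2.0)

    def test_permutation_invariance_over_runs(self, rng):
        mats = [ErrorMatrix(rng.uniform(0, 1, size=(3, 3))) for _ in range(4)]
        fwd = average_error_matrices(mats).values
        rev = average_error_matrices(mats[::-1]).values
        assert np.allclose(fwd, rev)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_error_matrices([ErrorMatrix(np.zeros((2, 2))),
                                    ErrorMatrix(np.zeros((3, 2)))])


class TestDetectOutliers:
    def _planted_matrix(self, rng, n_clean=100, outliers=(11, 47, 93)):
        E = 1.0 + 0.01 * rng.standard_normal((n_clean, 8))
        for r in outliers:
            E[r] = 50.0 + 0.5 * rng.standard_normal(8)
        return np.abs(E), sorted(outliers)

    def test_recovers_well_separated_rows(self, rng):
        E, planted = self._planted_matrix(rng)
        report = detect_outliers(ErrorMatrix(E), k=15)
        assert report.flagged == planted
        assert report.knee_found

    def test_all_identical_rows_flag_nothing(self):
        E = ErrorMatrix(np.full((40, 5), 2.0))
        with pytest.warns(UserWarning):
            report = detect_outliers(E, k=10)
        assert report.flagged == []
        assert not report.knee_found

    def test_row_permutation_equivariance(self, rng):
        E, planted = self._planted_matrix(rng)
        perm = rng.permutation(E.shape[0])
        report_p = detect_outliers(ErrorMatrix(E[perm]), k=15)
        remapped = sorted(np.where(np.isin(perm, planted))[0].tolist())
        assert report_p.flagged == remapped

    def test_scale_covariance_of_the_knee(self, rng):
        """A common rescaling of the error matrix leaves the flagged set
        unchanged (the knee threshold scales with the data)."""
        E, planted = self._planted_matrix(rng)
        r1 = detect_outliers(ErrorMatrix(E), k=15)
        r2 = detect_outliers(ErrorMatrix(E * 7.5), k=15)
        assert r1.flagged == r2.flagged
        assert r2.threshold == pytest.approx(7.5 * r1.threshold, rel=1e-9)

    def test_report_reproducibility(self, rng):
        E, _ = self._planted_matrix(rng)
        a = detect_outliers(ErrorMatrix(E), k=15)
        b = detect_outliers(ErrorMatrix(E), k=15)
        assert a.flagged == b.flagged and a.threshold == b.threshold

    def test_worst_channel_attribution(self, rng):
        E = np.abs(1.0 + 0.01 * rng.standard_normal((30, 4)))
        E[7, 2] = 60.0  # single-channel corruption
        report = detect_outliers(ErrorMatrix(E), k=5)
        assert report.flagged == [7]
        assert report.worst_channel[7] == 2

    def test_too_few_repetitions_rejected(self):
        with pytest.raises(ValueError):
            detect_outliers(ErrorMatrix(np.ones((10, 3))), k=15)


class TestKneedle:
    def test_flat_then_jump_knee_before_jump(self):
        y = np.r_[np.linspace(1.0, 1.05, 29), 50.0, 52.0, 55.0]
        idx = kneedle(y)
        assert idx is not None and 27 <= idx <= 29

    def test_constant_curve_has_no_knee(self):
        assert kneedle(np.ones(20)) is None


class TestTransitionPoint:
    def test_exponential_decay_elbow_in_expected_range(self, rng):
        epochs = np.arange(5, 85, 5)
        mean = 40.0 * np.exp(-epochs / 8.0) + 2.0
        mean = mean + 0.01 * rng.standard_normal(mean.size)
        std = np.full_like(mean, 0.1)
        tp = find_transition_point(epochs, mean, std)
        assert 15 <= tp.epoch <= 30

    def test_linear_curve_falls_back_to_last_checkpoint(self):
        epochs = np.arange(5, 45, 5)
        mean = 100.0 - 2.0 * epochs
        with pytest.warns(UserWarning):
            tp = find_transition_point(epochs, mean, np.ones_like(mean))
        assert tp.epoch == epochs[-1]

    def test_constant_curve_falls_back_to_first_checkpoint(self):
        epochs = np.arange(5, 45, 5)
        with pytest.warns(UserWarning):
            tp = find_transition_point(epochs, np.full(epochs.size, 3.0),
                                       np.ones(epochs.size))
        assert tp.epoch == epochs[0]

    def test_high_variance_checkpoints_excluded(self):
        epochs = np.arange(5, 85, 5)
        mean = 40.0 * np.exp(-epochs / 8.0) + 2.0
        std = np.full_like(mean, 0.1)
        # corrupt the spread exactly where the elbow would otherwise fall
        std[3:6] = 10.0
        tp = find_transition_point(epochs, mean, std)
        assert tp.epoch not in set(epochs[3:6])

    def test_too_few_checkpoints_rejected(self):
        with pytest.raises(ValueError):
            find_transition_point(np.array([5, 10, 15]), np.ones(3), np.ones(3))
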