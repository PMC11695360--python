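"""Spectral contracts of the clean generator and the artifact injections."""

import numpy as np
import pytest

from hveegnet.data import welch_psd
from hveegnet.synthetic import (ArtifactSpec, SpectralProfile, generate_clean,
                                inject_artifact, make_fixture)


@pytest.fixture(scope="module")
def benchmark_shaped_clean():
    return generate_clean(1, 8, 22, 1000, 250.0, seed=5)


class TestCleanSpectra:
    def test_alpha_band_dominates_mid_beta(self, benchmark_shaped_clean):
        """Mean 8-12 Hz power exceeds 1.5x the mean 14-18 Hz power when the
        alpha peak is set at 3x the 1/f baseline (the default profile)."""
        ds = benchmark_shaped_clean
        f, p = welch_psd(ds.values[0].reshape(-1, 1000), ds.fs)
        pm = p.mean(axis=0)
        ratio = pm[(f >= 8) & (f <= 12)].mean() / pm[(f >= 14) & (f <= 18)].mean()
        assert ratio >= 1.5

    def test_one_over_f_negative_loglog_slope(self, benchmark_shaped_clean):
        ds = benchmark_shaped_clean
        f, p = welch_psd(ds.values[0].reshape(-1, 1000), ds.fs)
        pm = p.mean(axis=0)
        sel = (f >= 2) & (f <= 40)
        slope = np.polyfit(np.log(f[sel]), np.log(pm[sel]), 1)[0]
        assert slope < 0

    def test_seed_determinism(self):
        a = generate_clean(1, 2, 3, 256, 128.0, seed=9)
        b = generate_clean(1, 2, 3, 256, 128.0, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_channels_standardized_to_nominal_rms(self, benchmark_shaped_clean):
        # channels share the subject gain around the 20-uV nominal RMS
        stds = benchmark_shaped_clean.values[0].std(axis=-1)
        assert np.all(stds > 0)
        assert stds.std() / stds.mean() < 0.05
        assert 5.0 < stds.mean() < 80.0  # microvolt scale, within gain spread

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            generate_clean(1, 1, 2, 256, 128.0,
                           profile=SpectralProfile(alpha_hz=100.0))


class TestArtifacts:
    def test_saturation_clamps_to_rail(self):
        ds = generate_clean(1, 4, 3, 256, 128.0, seed=1)
        spec = ArtifactSpec(kind="saturation", subject=0, repetition=2,
                            channels=(1,), onset=0.5, duration=1.0, magnitude=4.0)
        out = inject_artifact(ds, spec)
        span = slice(64, 192)
        rail = 4.0 * ds.profile.amplitude_rms
        assert np.all(np.abs(out.values[0, 2, 1, span]) == rail)
        assert len(np.unique(out.values[0, 2, 1, span])) == 1
        # untouched channels and repetitions unchanged
        assert np.array_equal(out.values[0, 0], ds.values[0, 0])

    def test_line_noise_power_at_50hz(self):
        ds = generate_clean(1, 2, 2, 1000, 250.0, seed=2)
        rms = ds.values[0, 0, 0].std()
        out = inject_artifact(ds, ArtifactSpec(
            kind="line_noise_50hz", subject=0, repetition=0, channels=(0,),
            magnitude=np.sqrt(10) * rms / ds.profile.amplitude_rms))
        f, p_dirty = welch_psd(out.values[0, 0, 0], 250.0)
        _, p_clean = welch_psd(ds.values[0, 0, 0], 250.0)
        bin50 = np.argmin(np.abs(f - 50.0))
        assert p_dirty[bin50] >= 10 * p_clean[bin50]

    def test_emg_concentrates_above_30hz(self):
        ds = generate_clean(1, 2, 2, 1000, 250.0, seed=3)
        out = inject_artifact(ds, ArtifactSpec(
            kind="emg_broadband", subject=0, repetition=1, channels=(1,),
            magnitude=5.0))
        f, pd = welch_psd(out.values[0, 1, 1], 250.0)
        _, pc = welch_psd(ds.values[0, 1, 1], 250.0)
        hi = f > 35
        assert pd[hi].mean() > 5 * pc[hi].mean()

    def test_blink_is_low_frequency(self):
        ds = generate_clean(1, 1, 2, 1000, 250.0, seed=4)
        out = inject_artifact(ds, ArtifactSpec(
            kind="blink_transient", subject=0, repetition=0, channels=(0,),
            onset=1.0, duration=2.0, magnitude=8.0))
        delta = out.values[0, 0, 0] - ds.values[0, 0, 0]
        spec = np.abs(np.fft.rfft(delta))
        freqs = np.fft.rfftfreq(1000, 1 / 250.0)
        assert spec[freqs < 4].sum() > 0.9 * spec.sum()

    def test_ground_truth_bookkeeping(self):
        ds = generate_clean(1, 4, 3, 256, 128.0, seed=1)
        out = inject_artifact(ds, ArtifactSpec(
            kind="saturation", subject=0, repetition=0, channels=(0,)))
        out = inject_artifact(out, ArtifactSpec(
            kind="blink_transient", subject=0, repetition=3, channels=(2,)))
        assert len(out.ground_truth) == 2
        assert set(out.ground_truth["kind"]) == {"saturation", "blink_transient"}

    def test_span_outside_segment_rejected(self):
        ds = generate_clean(1, 1, 2, 256, 128.0, seed=1)
        with pytest.raises(ValueError):
            inject_artifact(ds, ArtifactSpec(
                kind="saturation", subject=0, repetition=0, channels=(0,),
                onset=1.5, duration=2.0))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ArtifactSpec(kind="cosmic_ray", subject=0, repetition=0, channels=(0,))


class TestFixture:
    def test_tiny_shape_and_rate(self):
        ds = make_fixture("tiny", seed=0)
        assert ds.shape == (2, 32, 4, 128)
        assert len(ds.ground_truth) == int(0.03 * 64)  # floor of the 3% rate

    def test_benchmark_shape_and_artifact_count(self):
        ds = make_fixture("benchmark", seed=1)
        assert ds.shape == (1, 576, 22, 1000)
        assert len(ds.ground_truth) == 17  # floor(0.03 * 576)

    def test_fixture_determinism(self):
        a = make_fixture("tiny", seed=3)
        b = make_fixture("tiny", seed=3)
        assert np.array_equal(a.values, b.values)
        assert a.ground_truth.equals(b.ground_truth)

    def test_corruption_separates_from_clean(self):
        """A saturated copy of a segment sits at strictly positive DTW from
        the original, so the anomaly module has signal to find."""
        from hveegnet.dtw import normalized_dtw_score
        ds = generate_clean(1, 1, 2, 256, 128.0, seed=8)
        out = inject_artifact(ds, ArtifactSpec(
            kind="saturation", subject=0, repetition=0, channels=(0,),
            magnitude=3.0))
        score = normalized_dtw_score(ds.values[0, 0, 0], out.values[0, 0, 0])
        assert score > 0
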