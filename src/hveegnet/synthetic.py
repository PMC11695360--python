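"""Synthetic multi-channel EEG with controllable artifacts.

Clean channels are generated in the frequency domain: 1/f-shaped colored
noise (power ~ f^-exponent) plus narrowband alpha (~10 Hz) and beta
(~20 Hz) oscillations with randomized phases, a broadband noise floor, and
one shared slow oscillation giving the channels a common low-rank component
for spatial filters to exploit.  Channels are standardized to the profile's
nominal RMS; per-subject gains add inter-subject variability.

Channels carry EEG-realistic amplitudes (nominal RMS 20 microvolts; an
L1-cost DTW loss makes the amplitude scale part of the model's operating
point, so the generator matches the scale the autoencoders are tuned for).
Artifact magnitudes are specified as multiples of that nominal RMS.

Artifacts emulate the corruption classes seen in real motor-imagery
recordings: amplifier saturation (hard clamp at a rail), 50 Hz mains
contamination, broadband (>30 Hz) muscular activity and slow biphasic
eye-blink transients on frontal-like channels.  Every injection is recorded
in a ground-truth table so detection pipelines can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SpectralProfile", "ArtifactSpec", "SyntheticDataset",
           "generate_clean", "inject_artifact", "make_fixture"]

ARTIFACT_KINDS = ("saturation", "line_noise_50hz", "emg_broadband", "blink_transient")


@dataclass
class SpectralProfile:
    """Spectral recipe for clean EEG-like channels.

    Powers are relative to the local 1/f baseline at the peak center; the
    defaults give a clearly visible alpha peak (3x) and a weaker beta peak
    (1.5x), matching the usual appearance of clean resting EEG.
    """

    amplitude_rms: float = 20.0  # nominal channel RMS in microvolts
    oneoverf_exponent: float = 1.0
    alpha_hz: float = 10.0
    alpha_bw: float = 2.0
    alpha_rel_power: float = 3.0
    beta_hz: float = 20.0
    beta_bw: float = 4.0
    beta_rel_power: float = 1.5
    noise_floor: float = 0.02
    subject_gain_sd: float = 0.2
    shared_slow_hz: float = 1.5
    shared_slow_power: float = 0.3

    def validate(self, fs: float) -> None:
        if self.oneoverf_exponent <= 0:
            raise ValueError("1/f exponent must be positive")
        for f in (self.alpha_hz, self.beta_hz):
            if not (0 < f < fs / 2):
                raise ValueError(f"peak at {f} Hz outside (0, Nyquist={fs / 2}) Hz")


@dataclass
class ArtifactSpec:
    """One artifact injection: what, where and how strong.

    ``magnitude`` is expressed in multiples of the profile's nominal channel
    RMS: the saturation rail level, the sinusoid amplitude, the added-noise
    RMS, or the blink peak height.
    """

    kind: str
    subject: int
    repetition: int
    channels: tuple[int, ...]
    onset: float = 0.0
    duration: float | None = None  # None = to the end of the segment
    magnitude: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}; "
                             f"expected one of {ARTIFACT_KINDS}")
        if self.magnitude <= 0:
            raise ValueError("artifact magnitude must be positive")


@dataclass
class SyntheticDataset:
    """(subjects x repetitions x channels x time) EEG array + ground truth."""

    values: np.ndarray
    fs: float
    profile: SpectralProfile
    ground_truth: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["subject", "repetition", "channels", "kind", "onset",
                 "duration", "magnitude"]))
    seed: int | None = None

    @property
    def shape(self):
        return self.values.shape

    def segments(self, subject: int) -> np.ndarray:
        """One subject's repetitions as a model-ready (R, 1, C, T) batch."""
        return self.values[subject][:, None]


def _colored_channel(rng: np.random.Generator, T: int, fs: float,
                     p: SpectralProfile) -> np.ndarray:
    freqs = np.fft.rfftfreq(T, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    pos = freqs > 0
    amp[pos] = freqs[pos] ** (-p.oneoverf_exponent / 2.0)
    # narrowband peaks: Gaussian bumps on the *power* ratio around the center
    for f0, bw, rel in ((p.alpha_hz, p.alpha_bw, p.alpha_rel_power),
                        (p.beta_hz, p.beta_bw, p.beta_rel_power)):
        bump = rel * np.exp(-0.5 * ((freqs - f0) / bw) ** 2)
        amp[pos] *= np.sqrt(1.0 + bump[pos])
    amp[pos] += p.noise_floor
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if T % 2 == 0:
        spec[-1] = amp[-1]  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=T)
    return x / max(x.std(), 1e-12)


def generate_clean(n_subjects: int, n_trials: int, n_channels: int, T: int,
                   fs: float, profile: SpectralProfile | None = None,
                   seed: int = 0) -> SyntheticDataset:
    """Seed-deterministic clean dataset with the documented spectral shape."""
    profile = profile or SpectralProfile()
    profile.validate(fs)
    if T < 2 * fs:
        raise ValueError("segments should cover at least 2 s of signal")
    rng = np.random.default_rng(seed)
    out = np.empty((n_subjects, n_trials, n_channels, T))
    t = np.arange(T) / fs
    for s in range(n_subjects):
        gain = np.exp(rng.normal(0.0, profile.subject_gain_sd))
        for r in range(n_trials):
            shared = np.sqrt(profile.shared_slow_power) * np.sin(
                2 * np.pi * profile.shared_slow_hz * t + rng.uniform(0, 2 * np.pi))
            chan_gains = 1.0 + 0.1 * rng.standard_normal(n_channels)
            for c in range(n_channels):
                x = _colored_channel(rng, T, fs, profile) + shared * chan_gains[c]
                out[s, r, c] = profile.amplitude_rms * gain * x / max(x.std(), 1e-12)
    return SyntheticDataset(values=out, fs=fs, profile=profile, seed=seed)


def inject_artifact(dataset: SyntheticDataset, spec: ArtifactSpec) -> SyntheticDataset:
    """Return a copy of the dataset with one artifact injected and recorded."""
    fs = dataset.fs
    T = dataset.values.shape[-1]
    i0 = int(round(spec.onset * fs))
    dur = spec.duration if spec.duration is not None else (T - i0) / fs
    i1 = i0 + int(round(dur * fs))
    if not (0 <= i0 < i1 <= T):
        raise ValueError(f"artifact span [{i0}, {i1}) outside the segment [0, {T})")
    values = dataset.values.copy()
    seg = values[spec.subject, spec.repetition]
    amp = spec.magnitude * dataset.profile.amplitude_rms
    span = slice(i0, i1)
    nspan = i1 - i0
    rng = np.random.default_rng(np.random.SeedSequence(
        [dataset.seed or 0, ARTIFACT_KINDS.index(spec.kind),
         spec.subject, spec.repetition]))
    for c in spec.channels:
        if spec.kind == "saturation":
            seg[c, span] = amp * np.sign(seg[c, span].mean() or 1.0)
        elif spec.kind == "line_noise_50hz":
            t = np.arange(i0, i1) / fs
            seg[c, span] += amp * np.sin(2 * np.pi * 50.0 * t)
        elif spec.kind == "emg_broadband":
            noise = rng.standard_normal(nspan)
            spec_f = np.fft.rfft(noise)
            freqs = np.fft.rfftfreq(nspan, d=1.0 / fs)
            spec_f[freqs < 30.0] *= 0.05  # >30 Hz emphasis
            hp = np.fft.irfft(spec_f, n=nspan)
            seg[c, span] += amp * hp / max(hp.std(), 1e-12)
        elif spec.kind == "blink_transient":
            # biphasic low-frequency pulse (~1 Hz content)
            tt = np.linspace(-1, 1, nspan)
            pulse = tt * np.exp(-0.5 * (tt / 0.35) ** 2)
            seg[c, span] += amp * pulse / max(np.abs(pulse).max(), 1e-12)
    row = pd.DataFrame([{"subject": spec.subject, "repetition": spec.repetition,
                         "channels": ",".join(map(str, spec.channels)),
                         "kind": spec.kind, "onset": spec.onset,
                         "duration": dur, "magnitude": spec.magnitude}])
    gt = row if dataset.ground_truth.empty else pd.concat(
        [dataset.ground_truth, row], ignore_index=True)
    return replace(dataset, values=values, ground_truth=gt)


def make_fixture(scale: str = "tiny", seed: int = 0,
                 artifact_fraction: float = 0.03) -> SyntheticDataset:
    """Deterministic test datasets.

    ``tiny``: 2 subjects x 32 trials x 4 channels x 128 samples at 64 Hz
    (2-second segments; alpha/beta peaks stay below the 32 Hz Nyquist).
    ``benchmark``: 1 subject x 576 trials x 22 channels x 1000 samples at
    250 Hz.  A documented fraction (default 3%) of the repetitions carries a
    saturation artifact on a random channel subset.
    """
    if scale == "tiny":
        n_sub, n_tr, C, T, fs = 2, 32, 4, 128, 64.0
    elif scale == "benchmark":
        n_sub, n_tr, C, T, fs = 1, 576, 22, 1000, 250.0
    else:
        raise ValueError(f"unknown scale {scale!r}")
    ds = generate_clean(n_sub, n_tr, C, T, fs, seed=seed)
    rng = np.random.default_rng(seed + 1)
    n_bad = int(np.floor(artifact_fraction * n_sub * n_tr))
    flat = rng.choice(n_sub * n_tr, size=n_bad, replace=False)
    for idx in flat:
        s, r = divmod(int(idx), n_tr)
        chans = tuple(sorted(rng.choice(C, size=max(1, C // 2), replace=False).tolist()))
        ds = inject_artifact(ds, ArtifactSpec(
            kind="saturation", subject=s, repetition=r, channels=chans,
            onset=float(rng.uniform(0, 0.5)), duration=None,
            magnitude=10.0))
    return ds
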