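import numpy as np
import pytest

from hveegnet.models import ArchitectureConfig

TINY_ARCH = dict(n_channels=4, n_samples=128, temporal_kernel=32,
                 separable_kernel=16, z2_filter_kernel=17)


@pytest.fixture(scope="session")
def tiny_arch() -> ArchitectureConfig:
    """Scaled-down architecture for 4-channel, 128-sample segments."""
    return ArchitectureConfig(**TINY_ARCH)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240131)


def brute_force_dtw(a, b):
    """Independent oracle: exhaustive enumeration of all monotone warping
    paths, returning the minimum summed local cost.  Exponential — only for
    sequences of length <= ~6."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = [np.inf]

    def walk(i, j, acc):
        acc += abs(a[i] - b[j])
        if acc >= best[0]:
            return
        if i == len(a) - 1 and j == len(b) - 1:
            best[0] = acc
            return
        if i + 1 < len(a) and j + 1 < len(b):
            walk(i + 1, j + 1, acc)
        if j + 1 < len(b):
            walk(i, j + 1, acc)
        if i + 1 < len(a):
            walk(i + 1, j, acc)

    walk(0, 0, 0.0)
    return best[0]
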