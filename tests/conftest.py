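import numpy as np
import pytest

from fogsole.signals import CombinedSignal, SensorLayout


def bits_from_stances(duration_s: float, fs: float, stances, t0: float = 0.0) -> np.ndarray:
    """Binary contact vector that is 1 exactly on the given [a, b) intervals."""
    n = int(round(duration_s * fs))
    bits = np.zeros(n, dtype=np.uint8)
    for a, b in stances:
        lo = int(np.ceil((a - t0) * fs - 1e-9))
        hi = int(np.ceil((b - t0) * fs - 1e-9))
        bits[max(lo, 0) : min(hi, n)] = 1
    return bits


def comb(bits, foot: str = "left", fs: float = 32.0, t0: float = 0.0) -> CombinedSignal:
    return CombinedSignal(foot=foot, sampling_rate=fs, bits=np.asarray(bits, dtype=np.uint8), t0=t0)


def random_pair(rng: np.random.Generator, n: int, fs: float = 32.0):
    """Random bilateral contact signals built from variable-length runs."""

    def one(foot):
        bits = []
        value = int(rng.integers(0, 2))
        while len(bits) < n:
            run = int(rng.integers(1, 12))
            bits.extend([value] * run)
            value ^= 1
        return comb(np.array(bits[:n], dtype=np.uint8), foot=foot, fs=fs)

    return one("left"), one("right")


@pytest.fixture
def layout() -> SensorLayout:
    return SensorLayout.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
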