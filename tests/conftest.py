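import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from vigilnet.io_montage import MONTAGE_19, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_recording(rng):
    """Five-channel, 4 s, 500 Hz recording of independent noise."""
    labels = MONTAGE_19[:5]
    return Recording(labels, 500.0, rng.standard_normal((5, 2000)))


def sine_recording(freq: float, fs: float = 500.0, seconds: float = 4.0,
                   labels=("Fp1", "Fp2")) -> Recording:
    t = np.arange(int(seconds * fs)) / fs
    data = np.vstack([np.sin(2 * np.pi * freq * t + 0.3 * k)
                      for k in range(len(labels))])
    return Recording(labels, fs, data)
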