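import numpy as np
import pytest

from ismsm.eiip import EncodedSequence
from ismsm.fixtures import FixtureSpec, make_planted_sequence


def naive_dft_amplitudes(x, L):
    """Independent O(L^2) DFT oracle: |X(n)| for n = 1..L/2 of the
    mean-centered, zero-padded series."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    padded = np.zeros(L)
    padded[: len(x)] = x
    m = np.arange(L)
    amps = np.empty(L // 2)
    for n in range(1, L // 2 + 1):
        amps[n - 1] = abs(np.sum(padded * np.exp(-2j * np.pi * n * m / L)))
    return amps


@pytest.fixture
def planted_seq():
    """Noiseless on-grid cosine at bin 12 of a 128-sample series."""
    spec = FixtureSpec(
        kind="planted-sequence", seed=1, length=128, f0=12 / 128, noise_sd=0.0
    )
    seq, truth = make_planted_sequence(spec)
    return seq, truth


@pytest.fixture
def series_as_sequence():
    def _make(values, id="fx", kind="protein"):
        return EncodedSequence(id=id, kind=kind, values=tuple(float(v) for v in values))

    return _make
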