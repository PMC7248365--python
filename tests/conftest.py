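"""Shared fixtures: STFT configuration, separable fixtures, trained models.

The expensive fixtures (a trained separator on the disjoint-band data)
are session-scoped so that the convergence, capacity and pipeline tests
share one training run.
"""

import numpy as np
import pytest

from vocalmix import scenes, separator
from vocalmix.dsp import AudioSignal, STFTConfig

RATE = 44_100


@pytest.fixture(scope="session")
def default_cfg() -> STFTConfig:
    return STFTConfig()


@pytest.fixture(scope="session")
def disjoint_pair() -> separator.SourcePair:
    """Spectrally separable fixture: vocal < 1 kHz, instruments > 2 kHz."""
    return scenes.disjoint_band_pair(4.0, seed=0)


@pytest.fixture(scope="session")
def disjoint_holdout() -> separator.SourcePair:
    """A held-out mixture from the same disjoint-band distribution."""
    return scenes.disjoint_band_pair(4.0, seed=99)


@pytest.fixture(scope="session")
def trained_disjoint():
    """Separator trained 20 epochs (seed 0) on four disjoint-band tracks."""
    pairs = [scenes.disjoint_band_pair(4.0, seed=s) for s in range(4)]
    model, history = separator.train(pairs, separator.TrainConfig(epochs=20, seed=0))
    return model, history


@pytest.fixture(scope="session")
def small_model() -> separator.SeparatorModel:
    """A random-weight separator with a narrow hidden layer for pipeline tests."""
    cfg = STFTConfig()
    rng = np.random.default_rng(7)
    in_dim, hidden, out_dim = 3 * cfg.n_bins, 32, 2 * cfg.n_bins
    return separator.SeparatorModel(
        w1=rng.standard_normal((in_dim, hidden)) * 0.02,
        b1=rng.standard_normal(hidden) * 0.01,
        w2=rng.standard_normal((hidden, out_dim)) * 0.02,
        b2=rng.standard_normal(out_dim) * 0.01,
        input_scale=1.0,
        stft_config=cfg,
    )


def orthogonal_tones(n: int = RATE, rate: int = RATE) -> tuple[AudioSignal, AudioSignal]:
    """Two equal-RMS orthogonal signals (sines at different bin frequencies)."""
    t = np.arange(n) / rate
    a = np.sin(2 * np.pi * 441.0 * t)  # integer number of periods over 1 s
    b = np.sin(2 * np.pi * 882.0 * t)
    return AudioSignal(a, rate), AudioSignal(b, rate)
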