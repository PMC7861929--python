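import numpy as np
import pytest

from ecgstack.preprocess import denoise
from ecgstack.synth import SynthEcgConfig, balanced_class_sequence, synth_ecg


@pytest.fixture(scope="session")
def clean_mixed_record():
    """Noise-free 50-beat record covering all four classes, plus truth."""
    seq = balanced_class_sequence(50, seed=2)
    sig, truth = synth_ecg(SynthEcgConfig(n_beats=50, class_sequence=seq, seed=2))
    return sig, truth


@pytest.fixture(scope="session")
def denoised_mixed_record(clean_mixed_record):
    sig, truth = clean_mixed_record
    return denoise(sig), truth


@pytest.fixture(scope="session")
def blobs_400():
    """Separable 4-class Gaussian blobs: 100 per class, spread 0.1."""
    from ecgstack.synth import synth_feature_table

    X, y = synth_feature_table({c: 100 for c in "NSVF"}, spread=0.1, seed=7)
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
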