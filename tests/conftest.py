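import numpy as np
import pytest

from hrspls.io import standardize_columns
from hrspls.synthetic import generate_paired_omics


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_blocks():
    """Standardized 20x12 / 20x10 random blocks."""
    r = np.random.default_rng(7)
    X, _ = standardize_columns(r.standard_normal((20, 12)))
    Y, _ = standardize_columns(r.standard_normal((20, 10)))
    return X, Y


@pytest.fixture
def planted_blocks():
    """Standardized blocks with one planted co-module plus its truth."""
    X, Y, truth = generate_paired_omics(
        n_samples=60, p_features_x=80, q_features_y=70,
        support_size_x=10, support_size_y=10, snr=2.0, seed=11,
    )
    Xz, _ = standardize_columns(X)
    Yz, _ = standardize_columns(Y)
    return Xz, Yz, truth
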