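import numpy as np
import pytest

from o2weave import O2PLSConfig, OmicsBlock, SynthConfig, generate_joint_pair
from o2weave.preprocess import preprocess_pair


def random_centered_pair(seed, n=6, p=20, q=15):
    """Centered random Gaussian matrices sharing the sample axis."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, q))
    return X - X.mean(axis=0), Y - Y.mean(axis=0)


@pytest.fixture
def small_blocks():
    """A tiny paired-block fixture at study scale (6 samples)."""
    X, Y = random_centered_pair(7)
    samples = [f"S{i}" for i in range(6)]
    x = OmicsBlock("transcriptome", samples, [f"g{j}" for j in range(20)], X)
    y = OmicsBlock("metabolome", samples, [f"m{j}" for j in range(15)], Y)
    return x, y


HIGH_SNR = dict(
    var_joint_x=0.78, var_orth_x=0.2, var_noise_x=0.02,
    var_joint_y=0.78, var_orth_y=0.2, var_noise_y=0.02,
)


@pytest.fixture(scope="session")
def high_snr_fit():
    """A well-powered, low-noise synthetic pair with its preprocessed blocks."""
    cfg = SynthConfig(n_samples=50, p_features_x=200, q_features_y=100, seed=11, **HIGH_SNR)
    x, y, truth = generate_joint_pair(cfg)
    xt, yt, _, _ = preprocess_pair(x, y, uv_scale_y=False)
    return cfg, xt, yt, truth


@pytest.fixture
def o2pls_config():
    return O2PLSConfig(n_joint=3, n_orth_x=1, n_orth_y=1)
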