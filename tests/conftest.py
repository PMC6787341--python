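import numpy as np
import pytest

from rmtbi_markers.synthetic import (
    DEFAULT_5PL,
    SlideSimConfig,
    simulate_rppm_slide,
    spread_abundances,
)


@pytest.fixture(scope="session")
def noise_free_slide():
    """16-sample noise-free slide with an 8-fold abundance spread."""
    cfg = SlideSimConfig(n_samples=16, noise_sigma=0.0,
                         true_abundance=spread_abundances(16), seed=0)
    spots, truth = simulate_rppm_slide(cfg)
    return spots, truth, cfg


@pytest.fixture(scope="session")
def noisy_slide():
    """The recovery-oracle condition: 16 samples x 8 dilutions x 2
    depositions, sigma = 0.02 log10, seed 1."""
    cfg = SlideSimConfig(n_samples=16, noise_sigma=0.02, seed=1)
    spots, truth = simulate_rppm_slide(cfg)
    return spots, truth, cfg


@pytest.fixture(scope="session")
def truth_params():
    return DEFAULT_5PL


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
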