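import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small single-slice simulated dataset shared by slow-ish tests."""
    from spotview.synthdata import SynthSpec, generate

    spec = SynthSpec(grid_shape=(10, 10), n_domains=2, n_genes=60,
                     n_markers_per_domain=15, signal_strength=1.5,
                     dropout_p=0.2, seed=7)
    slices, domains, batches = generate(spec)
    return spec, slices, domains, batches
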