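import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Default-sized synthetic dataset with a causal site (module-scope cost ok)."""
    import haplogwas as h

    spec = h.SimSpec(
        n_strains=24,
        n_chromosomes=3,
        n_sites_per_chromosome=20,
        causal_site=25,
        strain_effect_sd=0.0,
        seed=7,
    )
    return spec, h.gen_dataset(spec)
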