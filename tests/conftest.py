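import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_midas():
    """A compact dialysis screen (100 metabolites x 12 proteins) with truth."""
    from allostery_screen.simulate import MidasSimConfig, gen_midas_dataset

    cfg = MidasSimConfig(n_metabolites=100, n_proteins=12, frac_enriched=0.05, seed=7)
    return gen_midas_dataset(cfg)
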