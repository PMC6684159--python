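import numpy as np
import pytest

from pleioaudit.synthetic import PanelSpec, gen_phenotype_panel


@pytest.fixture(scope="session")
def default_panel():
    """One synthetic 131-phenotype panel under the default study conditions."""
    return gen_phenotype_panel(PanelSpec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
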