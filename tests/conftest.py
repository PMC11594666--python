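import numpy as np
import pytest

from mitocms.fig3d import build_fig3d_fixture
from mitocms.synthetic_data import GeneratorConfig, generate_pair


@pytest.fixture(scope="session")
def fig3d():
    return build_fig3d_fixture()


@pytest.fixture(scope="session")
def default_pair():
    """One synthetic maintainer/CMS pair shared across tests."""
    config = GeneratorConfig(seed=11, genome_length=120_000)
    maintainer, ann, cms, cms_ann, truth = generate_pair(config)
    return {
        "config": config,
        "maintainer": maintainer,
        "maintainer_ann": ann,
        "cms": cms,
        "cms_ann": cms_ann,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
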