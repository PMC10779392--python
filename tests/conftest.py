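import numpy as np
import pytest

from mbmri.synthetic_cohort import default_region_table


@pytest.fixture(scope="session")
def coarse_table():
    """Coarse-scale region lookup: 14 regions per hemisphere."""
    return default_region_table(14)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
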