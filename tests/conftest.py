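import numpy as np
import pytest
from hypothesis import settings

from cytohts.dose_response import Fit4PL

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def unit_fit():
    """Exact 4PL with bottom 0, top 100, IC50 = 100 nM, hill 1."""
    return Fit4PL(bottom=0.0, top=100.0, log_ic50=2.0, hill=1.0,
                  rss=0.0, converged=True, n_points=32)


@pytest.fixture(scope="session")
def steep_fit():
    """Second reference curve: IC50 = 1 uM, hill 1.5."""
    return Fit4PL(bottom=0.0, top=100.0, log_ic50=3.0, hill=1.5,
                  rss=0.0, converged=True, n_points=32)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
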