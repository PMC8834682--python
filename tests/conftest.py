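import numpy as np
import pytest

from flimfret import AcquisitionConfig, ConditionDesign


@pytest.fixture(scope="session")
def config():
    """Default acquisition: 40 MHz, 256 channels over 25 ns, Gaussian IRF."""
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def small_config():
    """Coarse 64-channel grid for grid-search oracle tests."""
    return AcquisitionConfig(n_channels=64)


def make_design(name="cond", **kw):
    """Condition design shorthand with small-study defaults."""
    kw.setdefault("n_cells", 10)
    kw.setdefault("n_experiments", 1)
    return ConditionDesign(name=name, **kw)


@pytest.fixture
def donor_only_design():
    return make_design(
        "donor_only", binding_mean=0.0, acceptor_intensity_logmean=None
    )


@pytest.fixture
def wt_design():
    return make_design("WT+E47", binding_mean=0.5)
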