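import numpy as np
import pytest
from hypothesis import settings

from phdsq import datasets
from phdsq.pipeline import RunConfig, run_screen

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    """The default 39-pair, 31-gene synthetic panel (8 genes redundant)."""
    res = datasets.default_panel()
    assert not res.failures
    return res.panel


@pytest.fixture(scope="session")
def small_screen(tmp_path_factory):
    """A small end-to-end simulated screen shared by read-only tests.

    4 KF + 4 AD controls and 12 compounds at 2000 reads/well keeps the
    fixture fast while exercising every pipeline stage.
    """
    cfg = RunConfig(seed=11, out_dir=str(tmp_path_factory.mktemp("screen")),
                    n_kf=4, n_ad=4, n_compounds=12, reads_per_well=2000)
    return run_screen(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
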