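import numpy as np
import pytest

from cytomet import make_demo


@pytest.fixture(scope="session")
def demo_tables():
    """One default synthetic cohort (63 BD + 49 HC, 27 analytes), seed 1."""
    return make_demo(seed=1)


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """The same cohort written out as a CSV fixture directory."""
    d = tmp_path_factory.mktemp("demo")
    make_demo(seed=1, directory=d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
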