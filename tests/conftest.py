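import numpy as np
import pytest

from equiomics import StudyDesign, synthetic


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture(scope="session")
def dsrna():
    return synthetic.gen_dsrna(876, 0.5, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
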