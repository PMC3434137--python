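import numpy as np
import pytest

from mfnscan import CodingRegion, gen_coding_region, load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    """The packaged four-variant HR1 score table."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def hr1_like_region() -> CodingRegion:
    """A 44-codon synthetic region anchored at residue 391 (HR1-length span)."""
    return gen_coding_region(44, seed=20260101, name="hr1_like", first_residue_number=391)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(987654321)
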