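import numpy as np
import pytest

from rmanova import Design, enumerate_cells, enumerate_effects


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def design_2x3():
    return Design((2, 3), ("A", "B"))


@pytest.fixture
def effects_2x3(design_2x3):
    return {e.name: e for e in enumerate_effects(design_2x3)}


@pytest.fixture
def cells_2x3(design_2x3):
    return enumerate_cells(design_2x3)
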