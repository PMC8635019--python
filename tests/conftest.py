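import pytest

from pumpleak import preset, standard_rpmi_medium, reference_column
from pumpleak.scenarios import CELLS, VARIANTS

ALL_COLUMNS = [(cell, variant) for cell in CELLS for variant in VARIANTS]


@pytest.fixture(scope="session")
def standard_medium():
    return standard_rpmi_medium()


@pytest.fixture(scope="session")
def cell_a_full():
    """Balanced (state, params, medium) for cell A with every cotransporter."""
    return preset("A", "NC+KC+NKCC", refit=True)


@pytest.fixture(scope="session")
def cell_b_full():
    """Balanced (state, params, medium) for cell B with every cotransporter."""
    return preset("B", "NC+KC+NKCC", refit=True)


@pytest.fixture(scope="session")
def row_a_full():
    return reference_column("A", "NC+KC+NKCC")
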