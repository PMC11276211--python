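import numpy as np
import pytest

from flashox import FlashProtocol, normalize_to_y3, simulate_pattern
from flashox.fitting import fit_five_s
from flashox.presets import BIEXP_ROWS, FIVE_S_ROWS


@pytest.fixture(scope="session")
def standard_protocol():
    return FlashProtocol.standard()


@pytest.fixture(scope="session")
def noiseless_patterns(standard_protocol):
    """Y3-normalized noiseless patterns for the three preparations."""
    return {
        row: normalize_to_y3(simulate_pattern(params, standard_protocol))
        for row, params in FIVE_S_ROWS.items()
    }


@pytest.fixture(scope="session")
def five_s_fits(noiseless_patterns):
    """Full-multistart five-state fits of the noiseless row patterns.

    Session-scoped: these are the most expensive fits in the suite and are
    shared by the recovery and acceptance tests.
    """
    return {row: fit_five_s(pat) for row, pat in noiseless_patterns.items()}


@pytest.fixture(scope="session")
def row_params():
    return FIVE_S_ROWS


@pytest.fixture(scope="session")
def biexp_rows():
    return BIEXP_ROWS
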