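import numpy as np
import pytest

from gridcooccur import GridSpec, PresenceAbsenceMap, Window


@pytest.fixture
def unit_window():
    return Window.unit_square()


@pytest.fixture
def grid20(unit_window):
    return GridSpec(unit_window, 20, 20)


@pytest.fixture
def random_map_pair(grid20):
    """Two independent random occupancy maps on the 20x20 grid."""
    rng = np.random.default_rng(42)
    occ_a = rng.random((20, 20)) < 0.4
    occ_b = rng.random((20, 20)) < 0.6
    return (
        PresenceAbsenceMap(grid20, occ_a, "A"),
        PresenceAbsenceMap(grid20, occ_b, "B"),
    )
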