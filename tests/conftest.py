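import numpy as np
import pytest
from hypothesis import strategies as st

from assortld import GameteVector, PopulationState, hardy_weinberg_state


@pytest.fixture
def hw_half() -> PopulationState:
    """Hardy-Weinberg start with p0 = q0 = 1/2 and no disequilibrium."""
    return hardy_weinberg_state(0.5, 0.5, 0.0)


def _normalized(values, size):
    arr = np.asarray(values, dtype=float)
    total = arr.sum()
    return arr / total


@st.composite
def gamete_vectors(draw) -> GameteVector:
    """Random valid gamete-frequency vectors (weights normalised to 1)."""
    w = draw(
        st.lists(st.floats(0.01, 1.0, allow_nan=False), min_size=4, max_size=4)
    )
    return GameteVector(_normalized(w, 4))


@st.composite
def population_states(draw) -> PopulationState:
    """Random valid 10-genotype population states."""
    w = draw(
        st.lists(st.floats(0.001, 1.0, allow_nan=False), min_size=10, max_size=10)
    )
    return PopulationState(_normalized(w, 10))
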