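"""Shared fixtures: synthetic ground-truth systems at various sizes."""
import numpy as np
import pytest

from fvstates.synthetic import SyntheticSystem, generate_trajectory


@pytest.fixture(scope="session")
def system():
    return SyntheticSystem()


@pytest.fixture(scope="session")
def synthetic_result(system):
    """Medium synthetic trajectory visiting all three macrostates."""
    result = generate_trajectory(system, 3000, seed=202)
    assert len(np.unique(result.state_labels)) == system.n_states
    return result


@pytest.fixture(scope="session")
def small_result(system):
    """Short trajectory for O(n^2) clustering tests."""
    result = generate_trajectory(system, 400, seed=11)
    assert len(np.unique(result.state_labels)) == system.n_states
    return result
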