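import numpy as np
import pytest

from lcmediate.simulate import (
    CLASS_NAMES,
    P_M_GIVEN_X,
    P_Y_GIVEN_XM,
    SimScenario,
    generate_dataset,
    scenario,
)

# population cross-tabulation (counts per 5,000): cell order
# (class, M, Y) with Y-within-M-within-class
TABLE1_COUNTS = {
    # class index: ((M=0,Y=0), (M=0,Y=1), (M=1,Y=0), (M=1,Y=1))
    0: (150, 120, 50, 80),  # EOP
    1: (200, 125, 75, 100),  # AO
    2: (295, 180, 65, 60),  # CL
    3: (1950, 980, 325, 245),  # Low
}


@pytest.fixture(scope="session")
def table1_cells():
    """Weighted cell representation of the simulation population."""
    W, M, Y, wts = [], [], [], []
    for x, cells in TABLE1_COUNTS.items():
        for (m, y), c in zip(((0, 0), (0, 1), (1, 0), (1, 1)), cells):
            W.append(x)
            M.append(m)
            Y.append(y)
            wts.append(c)
    return (
        np.array(W),
        np.array(M, dtype=float),
        np.array(Y, dtype=float),
        np.array(wts, dtype=float),
    )


@pytest.fixture(scope="session")
def default_scenario():
    return SimScenario()


@pytest.fixture(scope="session")
def good_scenario():
    return scenario("good")


@pytest.fixture(scope="session")
def poor_scenario():
    return scenario("poor")


@pytest.fixture(scope="session")
def good_dataset(good_scenario):
    return generate_dataset(good_scenario, seed=2024)


@pytest.fixture(scope="session")
def separated_scenario():
    """Nearly perfectly separated classes: posteriors are one-hot."""
    profiles = np.where(np.array([
        [1, 1, 1, 1, 1],
        [0, 0, 1, 1, 1],
        [1, 1, 1, 0, 0],
        [0, 0, 0, 0, 0],
    ]) == 1, 0.99999, 0.00001)
    return SimScenario(item_profiles=profiles, entropy_label="separated", n_obs=3000)


@pytest.fixture(scope="session")
def separated_dataset(separated_scenario):
    return generate_dataset(separated_scenario, seed=7)
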