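import numpy as np
import pytest

from mrdoc import (
    ParameterVector,
    recovery_scenario,
    theta_from_scenario,
)


@pytest.fixture(scope="session")
def recovery_thetas() -> dict[int, ParameterVector]:
    """Generating parameter vectors of the three recovery scenarios."""
    return {i: theta_from_scenario(recovery_scenario(i)) for i in (1, 2, 3)}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_admissible_theta(rng: np.random.Generator, **fixed) -> ParameterVector:
    """A random parameter point inside the admissible region used for
    property tests (paths well away from bounds, moderate correlations)."""
    values = {
        "ra": rng.uniform(-0.6, 0.6),
        "rc": rng.uniform(-0.6, 0.6),
        "re": rng.uniform(-0.6, 0.6),
        **{n: rng.uniform(0.2, 0.9)
           for n in ("a_x", "c_x", "e_x", "a_y", "c_y", "e_y", "g1", "b1", "b2")},
        "g2": 0.0,
        "x": rng.uniform(0.5, 2.0),
    }
    values.update(fixed)
    return ParameterVector(**values)
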