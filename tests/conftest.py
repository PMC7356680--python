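import numpy as np
import pytest

import voxtab as vt


@pytest.fixture(scope="session")
def fixture_set():
    return vt.paper_formulations()


@pytest.fixture(scope="session")
def toy_grids():
    """Miniature grids of the four study dosage forms (shared, read-only)."""
    return vt.toy_tablets(seed=0)


@pytest.fixture
def soluble_component():
    def make(name="X", resistance=1, density=1.0, role=vt.Role.API):
        return vt.Component(
            name=name,
            weight_fraction=1.0,
            true_density=density,
            solubility_class=vt.SolubilityClass.SOLUBLE,
            dissolution_resistance=resistance,
            role=role,
        )

    return make


@pytest.fixture
def insoluble_component():
    return vt.Component(
        name="inert",
        weight_fraction=1.0,
        true_density=1.16,
        solubility_class=vt.SolubilityClass.INSOLUBLE,
        role=vt.Role.INERT_SEPARATOR,
    )


@pytest.fixture
def nw_times():
    """A 12-point grid spanning the rise of a first-order curve with k ~ 1e-3/s."""
    return np.linspace(300.0, 3600.0, 12)
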