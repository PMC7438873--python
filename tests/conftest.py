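import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from longdcm import datasets
from longdcm.growth import FixedEffects, GMatrix
from longdcm.measurement import ItemParameters, QMatrix
from longdcm.simulate import SimulationDesign, generate

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def qmatrix():
    return datasets.paper_qmatrix()


@pytest.fixture(scope="session")
def reference_items(qmatrix):
    return datasets.build_item_parameters(qmatrix)


@pytest.fixture(scope="session")
def fixed_even():
    return datasets.fixed_effects("even")


@pytest.fixture(scope="session")
def fixed_uneven():
    return datasets.fixed_effects("uneven")


@pytest.fixture(scope="session")
def g_equal():
    return datasets.g_matrix("equal")


@pytest.fixture(scope="session")
def g_unequal():
    return datasets.g_matrix("unequal")


@pytest.fixture(scope="session")
def two_attribute_item():
    """Reference two-attribute item: intercept -1.5, mains 1.5, interaction 0.5."""
    return ItemParameters(-1.5, {0: 1.5, 1: 1.5}, {(0, 1): 0.5})


def tiny_design(n_persons=30, n_occasions=3, seed=0, **overrides):
    """Small 9-item, 3-attribute design for fast end-to-end tests."""
    full = datasets.paper_qmatrix()
    q = QMatrix(full.entries[:9], item_ids=full.item_ids[:9],
                attribute_ids=full.attribute_ids)
    items = datasets.build_item_parameters(q)
    return SimulationDesign.from_factors(
        n_persons=n_persons, n_occasions=n_occasions, seed=seed,
        qmatrix=q, item_parameters=tuple(items), **overrides,
    )


@pytest.fixture()
def tiny_data():
    return generate(tiny_design(seed=7))


@pytest.fixture(scope="session")
def single_attribute_design():
    """K=1 design with 15 single-attribute items (exact-oracle tests)."""
    q = QMatrix(np.ones((15, 1), dtype=int))
    items = datasets.build_item_parameters(q)
    fixed = FixedEffects(gamma00=[-1.38], gamma10=[0.05], attribute_ids=("A1",))
    g = GMatrix(np.array([[0.15, 0.0173], [0.0173, 0.05]]), labels=("u0_A1", "u1_A1"))
    return SimulationDesign(
        n_persons=4, qmatrix=q, item_parameters=tuple(items),
        fixed_effects=fixed, g=g, n_occasions=3, seed=5,
    )
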