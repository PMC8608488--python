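import numpy as np
import pytest

from tumimm import (
    DivisionModel,
    GrowthLaw,
    ModelParams,
    Numerics,
    SizeGrid,
    GaussianSpec,
    TumorDensity,
    make_disc_grid,
)


@pytest.fixture(scope="session")
def disc64():
    return make_disc_grid(64)


@pytest.fixture(scope="session")
def disc32():
    return make_disc_grid(32)


@pytest.fixture
def size_grid():
    return SizeGrid(z_max=10.0, n_cells=256)


@pytest.fixture
def constant_law():
    return GrowthLaw(kind="constant", V_const=0.616)


@pytest.fixture
def gompertz_law():
    return GrowthLaw(kind="gompertz", r=0.616, b=10.0)


@pytest.fixture
def constant_division():
    return DivisionModel(rate_kind="constant", a=0.8)


@pytest.fixture
def random_density(size_grid):
    rng = np.random.default_rng(42)
    return TumorDensity(size_grid, rng.random(size_grid.n_cells))


def constant_coefficient_params(a: float = 0.8, **kw) -> ModelParams:
    """Validation setup: constant growth and division, no growth boost."""
    return ModelParams(
        growth=GrowthLaw(kind="constant", V_const=0.616),
        division=DivisionModel(rate_kind="constant", a=a),
        b1=GaussianSpec(0.0, 0.02),
        **kw,
    )


@pytest.fixture(scope="session")
def validation_run():
    """Long constant-coefficient run (a = 0.8): the reference equilibrium case.

    Session-scoped: reused by the equilibrium-phase, eigenvalue-constraint and
    predictor cross-validation tests.
    """
    from tumimm import run

    params = constant_coefficient_params()
    return params, run(params, Numerics(), horizon=150.0)
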