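import numpy as np
import pytest

from emflowtomo.phantom import (
    GridSpec,
    Phantom,
    PhantomConfig,
    build_phantom,
    default_config,
)
from emflowtomo.forward import ConductionSolver


@pytest.fixture(scope="session")
def small_phantom() -> Phantom:
    """Neck phantom at the small benchmark scale (21x21 reconstruction window)."""
    return build_phantom(default_config("small"))


@pytest.fixture(scope="session")
def small_solver(small_phantom) -> ConductionSolver:
    return ConductionSolver(small_phantom)


@pytest.fixture(scope="session")
def coarse_phantom() -> Phantom:
    return build_phantom(default_config("coarse"))


def make_uniform_phantom(n: int, sigma: float = 1.0) -> Phantom:
    """n x n unit-square phantom with uniform conductivity (for analytic
    solver checks); electrodes are placeholders along the bottom edge."""
    grid = GridSpec(nx=n, ny=n, dx=1.0 / n, dy=1.0 / n, origin=(0.5 / n, 0.5 / n))
    labels = np.full((n, n), 3, dtype=np.int8)  # muscle everywhere
    return Phantom(
        grid=grid,
        labels=labels,
        sigma=np.full((n, n), float(sigma)),
        electrodes=np.arange(12, dtype=np.int64),
        roi=(1, 1, 3, 3),
        config=PhantomConfig(grid=grid),
    )


@pytest.fixture
def uniform_phantom_factory():
    return make_uniform_phantom
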