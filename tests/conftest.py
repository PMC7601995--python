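import numpy as np
import pytest

from nanoqnar.crystal_builder import ConvergenceSpec, carve_sphere, neutralize, replicate_cell
from nanoqnar.fixtures import (
    SyntheticTableSpec,
    make_rocksalt,
    make_synthetic_table,
    toy_forcefield,
    toy_radii,
)
from nanoqnar.qnar_pipeline import TableSchema


@pytest.fixture(scope="session")
def rocksalt_cell():
    return make_rocksalt(a=4.2, metal="Mg", charge=2.0)


@pytest.fixture(scope="session")
def toy_ff():
    return toy_forcefield("Mg", 2.0)


@pytest.fixture(scope="session")
def radii():
    return toy_radii("Mg")


@pytest.fixture(scope="session")
def small_particle(rocksalt_cell):
    """Carved, neutral (unminimized) particle of ~60 atoms."""
    sup = replicate_cell(rocksalt_cell, (4, 4, 4))
    return neutralize(carve_sphere(sup, 6.0))


@pytest.fixture(scope="session")
def relaxed_particle(small_particle, toy_ff):
    from nanoqnar.crystal_builder import minimize_energy
    from nanoqnar.nanodescriptors import assign_regions

    p = minimize_energy(small_particle, toy_ff, ConvergenceSpec(max_iter=2000))
    with pytest.warns(UserWarning):
        return assign_regions(p, shell_depth=10.0)


@pytest.fixture(scope="session")
def synthetic_table():
    spec = SyntheticTableSpec(seed=11)
    table, roles = make_synthetic_table(spec)
    return table, TableSchema(roles)
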