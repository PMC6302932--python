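import numpy as np
import pytest

from boddkit import (
    RefinementConfig,
    build_connectivity,
    make_fixture,
    simulate_reflections,
)


@pytest.fixture(scope="session")
def water():
    return make_fixture("water_p1", seed=1)


@pytest.fixture(scope="session")
def carbonyl():
    return make_fixture("carbonyl_p1", seed=1)


@pytest.fixture(scope="session")
def ethane():
    return make_fixture("ethane_p1", seed=1)


@pytest.fixture(scope="session")
def methylamine():
    return make_fixture("methylamine_p1", seed=2)


@pytest.fixture(scope="session")
def mixed_metal():
    return make_fixture("mixed_metal_p1", seed=1)


@pytest.fixture(scope="session")
def water_conn(water):
    return build_connectivity(water.structure)


@pytest.fixture(scope="session")
def carbonyl_conn(carbonyl):
    return build_connectivity(carbonyl.structure)


@pytest.fixture(scope="session")
def water_refl(water):
    """Noise-free intensities from the water truth model."""
    return simulate_reflections(water, d_min=0.8, noise_fraction=0.0, seed=1)


@pytest.fixture(scope="session")
def carbonyl_refl(carbonyl):
    return simulate_reflections(carbonyl, d_min=0.8, noise_fraction=0.0, seed=1)


@pytest.fixture(scope="session")
def carbonyl_refl_noisy(carbonyl):
    return simulate_reflections(carbonyl, d_min=0.8, noise_fraction=0.02, seed=3)


def free_all_hydrogens(structure):
    """Copy with riding constraints removed (free-H refinement mode)."""
    st = structure.copy()
    for atom in st.atoms:
        atom.riding_parent = None
    return st


def zero_mean_perturbation(rng, n, scale):
    """Coordinate perturbations with the floating-origin component removed."""
    pert = rng.uniform(-scale, scale, size=(n, 3))
    return pert - pert.mean(axis=0)


@pytest.fixture
def iam_config():
    return RefinementConfig.iam_mode()
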