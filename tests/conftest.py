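import pytest

from corelattice import (
    NON_OCCLUDING_RULE,
    OCCLUDING_RULE,
    build_core,
    rotation_group,
)


@pytest.fixture(scope="session")
def dodeca():
    return build_core("icosahedral-60mer")


@pytest.fixture(scope="session")
def dodeca_group(dodeca):
    return rotation_group(dodeca)


@pytest.fixture(scope="session")
def cube():
    return build_core("octahedral-24mer")


@pytest.fixture(scope="session")
def cube_group(cube):
    return rotation_group(cube)


@pytest.fixture(scope="session")
def rule3():
    return OCCLUDING_RULE


@pytest.fixture(scope="session")
def rule2():
    return NON_OCCLUDING_RULE


@pytest.fixture(scope="session")
def tetra_classes(dodeca, dodeca_group, rule3):
    """The two size-4 (tetrahedral saturated) configuration classes."""
    from corelattice import enumerate_classes

    return enumerate_classes(dodeca, dodeca_group, rule3, 4)


@pytest.fixture(scope="session")
def inversion_partner(dodeca):
    """Vertex permutation induced by the central inversion x -> -x."""
    import numpy as np

    coords = dodeca.coords
    perm = []
    for v in dodeca.vertices:
        hits = np.where(np.linalg.norm(coords + coords[v], axis=1) < 1e-9)[0]
        assert hits.size == 1
        perm.append(int(hits[0]))
    return tuple(perm)
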