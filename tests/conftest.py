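import numpy as np
import pytest

from circgcn import AssociationMatrix, SyntheticSpec, worked_example


@pytest.fixture(scope="session")
def micro():
    """Documentation micro-fixture: 2x2 identity AM + 3-disease chain."""
    return worked_example()


@pytest.fixture()
def diag3():
    return AssociationMatrix(
        ["c1", "c2", "c3"], ["d1", "d2", "d3"], np.eye(3, dtype=np.int8)
    )


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast synthetic benchmark used in pipeline smoke tests."""
    return SyntheticSpec(
        n_circ=40, n_dis=12, n_blocks=2, within_density=0.5,
        background_density=0.03, seed=7,
    )
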