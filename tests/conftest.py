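import numpy as np
import pytest

from hesspot.descriptor import AEVSpec
from hesspot.structures import LabeledStructure


@pytest.fixture(scope="session")
def small_spec():
    """Compact descriptor used throughout the unit tests."""
    return AEVSpec(elements=("H", "C", "O"),
                   cutoff=4.6,
                   radial_shifts=tuple(np.linspace(0.7, 2.6, 6)),
                   angular_theta_shifts=(0.0, np.pi / 2, np.pi),
                   angular_radial_shifts=(1.0, 1.9))


@pytest.fixture
def bent_molecule():
    """A 4-atom bent molecule with no near-collinear triples."""
    coords = np.array([[0.0, 0.0, 0.0],
                       [1.1, 0.0, 0.0],
                       [1.6, 1.0, 0.2],
                       [-0.4, 0.9, -0.5]])
    return LabeledStructure(("O", "C", "H", "H"), coords)


@pytest.fixture
def triatomic():
    coords = np.array([[1.2, 0.0, 0.0],
                       [0.0, 0.0, 0.0],
                       [-0.3, 1.1, 0.0]])
    return LabeledStructure(("H", "C", "O"), coords)
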