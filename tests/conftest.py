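import numpy as np
import pytest

from loopflex import ToySystemSpec, Well
from loopflex.structure_io import BackboneChain, _embed_frame


@pytest.fixture
def double_well_1d():
    """Asymmetric 1D double well: depths 2 and 4 kT at -pi/2 and +pi/2."""
    return ToySystemSpec(1, [Well((-np.pi / 2,), 2.0, 0.5),
                             Well((np.pi / 2,), 4.0, 0.5)], seed=7)


@pytest.fixture
def symmetric_double_well_1d():
    return ToySystemSpec(1, [Well((-np.pi / 2,), 3.0, 0.5),
                             Well((np.pi / 2,), 3.0, 0.5)], seed=11)


def ideal_backbone(psi_values):
    """Synthetic backbone with exactly known psi dihedrals.

    Nine chain points (N CA C) x 3 residues are placed by internal
    coordinates (bond 1.5 A, angle 115 deg); chain dihedrals 0 and 3 are
    the psi torsions of residues 0 and 1, the others are trans.
    """
    torsions = np.full(6, np.pi)
    torsions[0] = psi_values[0]
    torsions[3] = psi_values[1]
    pts = _embed_frame(torsions, bond=1.5, theta=np.deg2rad(115.0))
    coords = pts.reshape(3, 3, 3)
    return BackboneChain(("10", "11", "12"), coords, chain_id="H")


@pytest.fixture
def backbone_chain():
    return ideal_backbone([-1.0, 2.2])
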