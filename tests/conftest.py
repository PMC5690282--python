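import numpy as np
import pytest

from intarch import clms, data, synthetic
from intarch.structures import (
    Assembly,
    AssemblyComponent,
    Atom,
    Residue,
    RigidTransform,
    Structure,
)


@pytest.fixture(scope="session")
def table4_csms():
    return clms.parse_csm_table(data.bs3_crosslink_text(), dialect="paper_table")


@pytest.fixture(scope="session")
def table2_peptides():
    from intarch import hdx

    return hdx.parse_hdx_table(data.hdx_deuteration_text())


def ca_chain(coords, chain="A", start=1):
    """Cα-only residue list from an (n, 3) array."""
    return [
        Residue(start + i, "", "ALA", [Atom("CA", "C", np.asarray(c, dtype=float))])
        for i, c in enumerate(np.asarray(coords, dtype=float))
    ]


def ca_structure(coords, id="toy", chain="A", start=1):
    return Structure(id, {chain: ca_chain(coords, chain, start)})


@pytest.fixture
def line_structure():
    """3 residues with Cα at (0,0,0), (3.8,0,0), (7.6,0,0)."""
    return ca_structure([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])


@pytest.fixture(scope="session")
def toy_scenario():
    return synthetic.Scenario(seed=11, receptor_size=60, mobile_size=40)


@pytest.fixture(scope="session")
def toy_complex(toy_scenario):
    return synthetic.make_toy_complex(toy_scenario)


def random_transform(rng) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return RigidTransform(Rotation.from_quat(q).as_matrix(), rng.normal(0, 20, 3))


def single_component_assembly(structure, label="model"):
    return Assembly([AssemblyComponent(label, structure, RigidTransform.identity())])
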