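"""Shared fixtures: small handwritten structures and cached synthetic fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from spiroscan.structure_model import Atom, Residue, Structure, VDW_RADII

TOY_PDB = """\
HEADER    TOY
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""


def build_structure(spec, structure_id="test"):
    """Build a Structure from {chain: [(resnum, resname, [(atom, element, xyz), ...]), ...]}."""
    st = Structure(id=structure_id)
    serial = 1
    for chain_id, residues in spec.items():
        out = []
        for resnum, resname, atoms in residues:
            res = Residue(chain_id=chain_id, number=resnum, insertion_code="", name=resname)
            for name, element, xyz in atoms:
                res.atoms.append(Atom(serial=serial, name=name, element=element,
                                      coord=np.asarray(xyz, float),
                                      vdw_radius=VDW_RADII[element]))
                serial += 1
            out.append(res)
        st.chains[chain_id] = out
    return st


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture(scope="session")
def multimer():
    from spiroscan.synthetic_data import make_toy_multimer
    return make_toy_multimer(seed=11, n_salt_bridges=2, n_hbonds=3)


@pytest.fixture(scope="session")
def sealed_phantom():
    from spiroscan.synthetic_data import make_channel_phantom
    return make_channel_phantom(seed=21)


@pytest.fixture(scope="session")
def windowed_phantom():
    from spiroscan.synthetic_data import make_channel_phantom
    return make_channel_phantom(seed=22, window={"s": 0.5, "aperture": 1.5})


@pytest.fixture(scope="session")
def sealed_tunnel(sealed_phantom):
    from spiroscan.tunnel_finder import find_tunnel
    st, truth = sealed_phantom
    cl = np.asarray(truth.truth["centerline"])
    tun = find_tunnel(st, cl[0] + [2.5, 0, 0], cl[-1] - [2.5, 0, 0])
    assert tun is not None
    return tun


@pytest.fixture(scope="session")
def windowed_tunnel(windowed_phantom):
    from spiroscan.tunnel_finder import find_tunnel
    st, truth = windowed_phantom
    cl = np.asarray(truth.truth["centerline"])
    tun = find_tunnel(st, cl[0] + [2.5, 0, 0], cl[-1] - [2.5, 0, 0])
    assert tun is not None
    return tun
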