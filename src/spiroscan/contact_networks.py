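"""Inter-protomer salt bridges and hydrogen bonds between chain groups.

Spirosome stability tracks with the density of polar contacts across the
oligomerisation interfaces: extended spirosomes carry more inter-protomer
salt bridges and a wider variety of hydrogen-bonded residue pairs than
compact ones.  This module detects both contact classes between two chain
groups under explicit, documented geometric criteria (all heavy-atom; the
deposited structures carry no hydrogens):

* salt bridge — any basic side-chain nitrogen of Arg/Lys/His within
  ``cutoff`` (default 4.0 Å) of any carboxylate oxygen of Asp/Glu on the
  other group; one contact per residue pair at the minimum distance.
* hydrogen bond — donor/acceptor heavy-atom pair (N/O/S donors, N/O
  acceptors, main chain and side chain) within ``d_max`` (default 3.5 Å);
  optionally filtered by an antecedent-atom angle >= 90°.

His is treated as a potential salt-bridge donor by default (protonation is
unknown in the deposited models); pass ``his_as_donor=False`` to switch it
off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import Residue, Structure, StructureError

__all__ = [
    "ContactPair",
    "find_salt_bridges",
    "find_hbonds",
    "unique_residue_pairs",
    "SALT_BRIDGE_BASIC",
    "SALT_BRIDGE_ACIDIC",
    "HBOND_DONORS",
    "HBOND_ACCEPTORS",
]

# side-chain nitrogens that can carry a positive charge
SALT_BRIDGE_BASIC: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
# side-chain carboxylate oxygens
SALT_BRIDGE_ACIDIC: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

# Hydrogen-bond chemistry by residue.  Backbone N is a donor and backbone
# O/OXT an acceptor for every standard residue; the tables below add the
# side-chain atoms.  Hydroxyls (Ser/Thr/Tyr) and His ring nitrogens act as
# both donor and acceptor.
_SC_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "TRP": ("NE1",),
    "CYS": ("SG",),
}
_SC_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}

# antecedent (covalently bonded heavy atom) used for the optional angle test
_ANTECEDENT: dict[str, str] = {
    "N": "CA", "O": "C", "OXT": "C",
    "NE": "CD", "NH1": "CZ", "NH2": "CZ", "NZ": "CE",
    "ND1": "CG", "NE2": "CD2", "ND2": "CG", "OG": "CB", "OG1": "CB",
    "OH": "CZ", "NE1": "CD1", "SG": "CB",
    "OD1": "CG", "OD2": "CG", "OE1": "CD", "OE2": "CD",
    "SD": "CG",
}
# NE2 antecedent differs between His (CD2/CE1) and Gln (CD); Gln handled here
_ANTECEDENT_BY_RES: dict[tuple[str, str], str] = {
    ("GLN", "NE2"): "CD",
    ("HIS", "NE2"): "CD2",
    ("HIS", "ND1"): "CG",
}

HBOND_DONORS = _SC_DONORS
HBOND_ACCEPTORS = _SC_ACCEPTORS


@dataclass(frozen=True)
class ContactPair:
    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    resname_a: str
    resname_b: str
    atom_a: str
    atom_b: str
    distance: float
    kind: str  # "salt_bridge" | "hbond"
    angle: Optional[float] = None  # degrees, hbond antecedent angle when computed


def _check_groups(structure: Structure, group_a: Iterable[str], group_b: Iterable[str]):
    a, b = list(group_a), list(group_b)
    overlap = set(a) & set(b)
    if overlap:
        raise StructureError(f"chain groups overlap: {sorted(overlap)}")
    for cid in a + b:
        if cid not in structure.chains:
            raise StructureError(f"chain {cid!r} not present in structure {structure.id!r}")
    return a, b


def _collect(structure: Structure, chain_ids, table, backbone=()):
    """(residue, atom) records for the atoms named by a residue->atoms table."""
    recs = []
    for res in structure.residues(chain_ids):
        if not res.is_standard:
            continue
        names = set(table.get(res.name, ()))
        names.update(n for n in backbone if res.has_atom(n))
        for a in res.atoms:
            if a.name in names:
                recs.append((res, a))
    return recs


def _pairs_within(recs_a, recs_b, cutoff: float):
    """All cross pairs within cutoff, via a KD-tree on the second set."""
    if not recs_a or not recs_b:
        return
    coords_b = np.array([a.coord for _, a in recs_b])
    tree = cKDTree(coords_b)
    for res_a, atom_a in recs_a:
        for j in tree.query_ball_point(atom_a.coord, cutoff):
            res_b, atom_b = recs_b[j]
            d = float(np.linalg.norm(atom_a.coord - atom_b.coord))
            if d <= cutoff:
                yield res_a, atom_a, res_b, atom_b, d


def _dedupe_min_distance(raw: list[ContactPair]) -> list[ContactPair]:
    """Keep one contact per (residue_a, residue_b) pair: the closest."""
    best: dict[tuple, ContactPair] = {}
    for c in raw:
        key = (c.residue_a, c.residue_b)
        if key not in best or c.distance < best[key].distance:
            best[key] = c
    return sorted(best.values(), key=lambda c: (c.residue_a, c.residue_b))


def find_salt_bridges(
    structure: Structure,
    group_a: Iterable[str],
    group_b: Iterable[str],
    cutoff: float = 4.0,
    his_as_donor: bool = True,
) -> list[ContactPair]:
    """Inter-group salt bridges (basic N vs carboxylate O, either direction)."""
    a, b = _check_groups(structure, group_a, group_b)
    basic = dict(SALT_BRIDGE_BASIC)
    if not his_as_donor:
        basic.pop("HIS")
    raw: list[ContactPair] = []
    for grp_pos, grp_neg, flip in ((a, b, False), (b, a, True)):
        pos = _collect(structure, grp_pos, basic)
        neg = _collect(structure, grp_neg, SALT_BRIDGE_ACIDIC)
        for res_p, atom_p, res_n, atom_n, d in _pairs_within(pos, neg, cutoff):
            res_a, atom_a, res_b, atom_b = (res_n, atom_n, res_p, atom_p) if flip else (res_p, atom_p, res_n, atom_n)
            raw.append(ContactPair(
                residue_a=res_a.id, residue_b=res_b.id,
                resname_a=res_a.name, resname_b=res_b.name,
                atom_a=atom_a.name, atom_b=atom_b.name,
                distance=d, kind="salt_bridge",
            ))
    return _dedupe_min_distance(raw)


def _antecedent_coord(res: Residue, atom_name: str) -> Optional[np.ndarray]:
    ante = _ANTECEDENT_BY_RES.get((res.name, atom_name), _ANTECEDENT.get(atom_name))
    if ante is not None and res.has_atom(ante):
        return res.atom(ante).coord
    return None


def find_hbonds(
    structure: Structure,
    group_a: Iterable[str],
    group_b: Iterable[str],
    d_max: float = 3.5,
    require_geometry: bool = False,
    min_angle: float = 90.0,
) -> list[ContactPair]:
    """Inter-group heavy-atom hydrogen bonds (donor on either side).

    With ``require_geometry`` the antecedent-donor-acceptor angle must be
    >= ``min_angle`` degrees (a hydrogen pointing roughly toward the
    acceptor is then geometrically possible); donors with no resolvable
    antecedent atom pass the filter.
    """
    a, b = _check_groups(structure, group_a, group_b)
    raw: list[ContactPair] = []
    for grp_don, grp_acc, flip in ((a, b, False), (b, a, True)):
        donors = _collect(structure, grp_don, _SC_DONORS, backbone=("N",))
        acceptors = _collect(structure, grp_acc, _SC_ACCEPTORS, backbone=("O", "OXT"))
        for res_d, atom_d, res_ac, atom_ac, d in _pairs_within(donors, acceptors, d_max):
            angle = None
            ante = _antecedent_coord(res_d, atom_d.name)
            if ante is not None:
                v1 = ante - atom_d.coord
                v2 = atom_ac.coord - atom_d.coord
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom > 0:
                    angle = float(np.degrees(np.arccos(np.clip(v1 @ v2 / denom, -1.0, 1.0))))
            if require_geometry and angle is not None and angle < min_angle:
                continue
            res_a, atom_a, res_b, atom_b = (res_ac, atom_ac, res_d, atom_d) if flip else (res_d, atom_d, res_ac, atom_ac)
            raw.append(ContactPair(
                residue_a=res_a.id, residue_b=res_b.id,
                resname_a=res_a.name, resname_b=res_b.name,
                atom_a=atom_a.name, atom_b=atom_b.name,
                distance=d, kind="hbond", angle=angle,
            ))
    return _dedupe_min_distance(raw)


def unique_residue_pairs(contacts: list[ContactPair]) -> int:
    """Number of distinct unordered residue pairs among the contacts."""
    return len({frozenset((c.residue_a, c.residue_b)) for c in contacts})
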