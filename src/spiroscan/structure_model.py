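"""Macromolecular structure container, I/O and rigid-body superposition.

The container is deliberately small: chains -> residues -> atoms with author
numbering preserved, heavy-atom van der Waals radii attached at load time,
and waters/ligands kept but flagged hetero.  Reading and writing of PDB and
mmCIF goes through :mod:`gemmi`; this module only normalises the result
(single conformer per residue, element radii resolved) so that every
downstream geometric count is deterministic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "StructureError",
    "ParseError",
    "SelectionError",
    "VDW_RADII",
    "load_structure",
    "write_structure",
    "select_group",
    "kabsch_superpose",
    "superpose_chains",
    "parse_selection",
    "THREE_TO_ONE",
]


class StructureError(ValueError):
    """Invalid structure content (unknown element, empty selection, ...)."""


class ParseError(StructureError):
    """A file could not be parsed in the requested dialect."""


class SelectionError(KeyError):
    """A chain/residue/atom selection did not resolve."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep it readable
        return self.args[0] if self.args else ""


# Bondi-style van der Waals radii in Å, applied uniformly to every structure.
# Main-group values follow Bondi (1964); first-row transition metals use the
# commonly tabulated crystallographic values.  Hydrogens are listed for
# completeness but all analyses here are heavy-atom only.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20,
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "B": 1.92,
    "FE": 2.00, "ZN": 1.39, "MG": 1.73, "MN": 2.05, "CU": 1.40,
    "NI": 1.63, "CO": 2.00, "NA": 2.27, "K": 2.75, "CA": 2.31,
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    vdw_radius: float
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(
                f"atom {self.serial} ({self.name}): coordinates must be a finite 3-vector"
            )
        if self.vdw_radius <= 0:
            raise StructureError(f"atom {self.serial} ({self.name}): vdw radius must be > 0")


@dataclass
class Residue:
    chain_id: str
    number: int
    insertion_code: str  # "" when absent
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def one_letter(self) -> Optional[str]:
        return THREE_TO_ONE.get(self.name)

    @property
    def is_standard(self) -> bool:
        return self.name in THREE_TO_ONE

    @property
    def is_water(self) -> bool:
        return self.name in _WATER_NAMES

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise SelectionError(f"atom {name!r} not found in {self.chain_id}:{self.number}{self.insertion_code}:{self.name}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self, chain_ids: Optional[Iterable[str]] = None) -> Iterator[Residue]:
        ids = self.chain_ids if chain_ids is None else list(chain_ids)
        for cid in ids:
            yield from self.chains[cid]

    def atoms(self, chain_ids: Optional[Iterable[str]] = None) -> Iterator[Atom]:
        for res in self.residues(chain_ids):
            yield from res.atoms

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        if chain_id not in self.chains:
            raise SelectionError(f"chain {chain_id!r} not present in structure {self.id!r}")
        for res in self.chains[chain_id]:
            if res.number == number and res.insertion_code == icode:
                return res
        raise SelectionError(f"residue {chain_id}:{number}{icode} not present in structure {self.id!r}")

    def coordinates(
        self,
        chain_ids: Optional[Iterable[str]] = None,
        include_hetero: bool = False,
        include_waters: bool = False,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Stacked coordinates and radii of the selected protein atoms.

        Waters and non-polymer heteroatoms are excluded unless asked for.
        Returns ``(coords (n,3), radii (n,))``.
        """
        coords, radii = [], []
        for res in self.residues(chain_ids):
            if res.is_water and not include_waters:
                continue
            for a in res.atoms:
                if a.is_hetero and not res.is_water and not include_hetero:
                    continue
                if a.is_hetero and res.is_water and not include_waters:
                    continue
                coords.append(a.coord)
                radii.append(a.vdw_radius)
        if not coords:
            return np.empty((0, 3)), np.empty((0,))
        return np.asarray(coords, dtype=float), np.asarray(radii, dtype=float)

    def chain_sequence(self, chain_id: str) -> tuple[str, list[Residue]]:
        """One-letter sequence of a chain's standard residues, with the residues."""
        if chain_id not in self.chains:
            raise SelectionError(f"chain {chain_id!r} not present in structure {self.id!r}")
        seq, residues = [], []
        for res in self.chains[chain_id]:
            if res.is_standard:
                seq.append(THREE_TO_ONE[res.name])
                residues.append(res)
        return "".join(seq), residues


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _detect_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f not in ("pdb", "mmcif", "cif"):
            raise ValueError(f"unknown structure format {fmt!r} (expected 'pdb' or 'mmcif')")
        return "pdb" if f == "pdb" else "mmcif"
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def load_structure(path: str | Path, fmt: Optional[str] = None, keep_waters: bool = True) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Author residue numbering and insertion codes are preserved.  Alternate
    locations are collapsed to the highest-occupancy conformer.  Waters are
    retained (flagged hetero) unless ``keep_waters`` is false.  An atom whose
    element is missing from the radius table raises :class:`StructureError`
    naming the atom.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    kind = _detect_format(path, fmt)
    try:
        if kind == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: could not parse as {kind}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise ParseError(f"{path}: file contains no models")
    model = st[0]

    out = Structure(id=st.name or path.stem, metadata={"source": str(path), "format": kind})
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            # collapse altlocs: keep the highest-occupancy atom per name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            is_het = res.het_flag == "H"
            r = Residue(
                chain_id=chain.name,
                number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                name=res.name.strip(),
            )
            for atom in res:
                if best.get(atom.name) is not atom:
                    continue
                elem = atom.element.name.upper()
                if elem not in VDW_RADII:
                    raise StructureError(
                        f"{path}: unknown element {atom.element.name!r} for atom "
                        f"serial {atom.serial} ({chain.name}:{res.seqid.num}:{atom.name})"
                    )
                r.atoms.append(
                    Atom(
                        serial=atom.serial,
                        name=atom.name,
                        element=elem,
                        coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        vdw_radius=VDW_RADII[elem],
                        is_hetero=is_het,
                    )
                )
            if r.is_water and not keep_waters:
                continue
            if r.atoms:
                residues.append(r)
        if residues:
            out.chains.setdefault(chain.name, []).extend(residues)
    if not out.chains:
        raise ParseError(f"{path}: no atoms found")
    return out


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for cid, residues in structure.chains.items():
        chain = gemmi.Chain(cid)
        for res in residues:
            g = gemmi.Residue()
            g.name = res.name
            g.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            g.het_flag = "H" if (res.atoms and res.atoms[0].is_hetero) else "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.serial = a.serial
                ga.element = gemmi.Element(a.element.capitalize())
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = 1.0
                g.add_atom(ga)
            chain.add_residue(g)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path, fmt: Optional[str] = None) -> None:
    """Write a structure as PDB or mmCIF (format inferred from the suffix)."""
    path = Path(path)
    kind = _detect_format(path, fmt)
    st = _to_gemmi(structure)
    if kind == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_group(structure: Structure, chain_ids: Iterable[str]) -> Structure:
    """Sub-structure containing exactly the requested chains, atoms unchanged."""
    wanted = list(chain_ids)
    missing = [c for c in wanted if c not in structure.chains]
    if missing:
        raise SelectionError(
            f"chain(s) {', '.join(repr(c) for c in missing)} not present in structure {structure.id!r}"
        )
    sub = Structure(id=structure.id, metadata=dict(structure.metadata))
    for cid in wanted:
        sub.chains[cid] = copy.deepcopy(structure.chains[cid])
    return sub


def parse_selection(structure: Structure, spec: str) -> np.ndarray:
    """Resolve a ``chain[:resnum[:atomname]]`` selection to a coordinate.

    Returns the atom coordinate, the residue centroid, or the chain centroid
    depending on how specific the selection is.
    """
    parts = spec.split(":")
    if not 1 <= len(parts) <= 3 or not parts[0]:
        raise SelectionError(f"bad selection {spec!r}; expected chain[:resnum[:atomname]]")
    cid = parts[0]
    if cid not in structure.chains:
        raise SelectionError(f"chain {cid!r} not present in structure {structure.id!r}")
    if len(parts) == 1:
        pts = np.array([a.coord for a in structure.atoms([cid])])
        return pts.mean(axis=0)
    try:
        num = int(parts[1])
    except ValueError as exc:
        raise SelectionError(f"bad residue number in selection {spec!r}") from exc
    res = structure.residue(cid, num)
    if len(parts) == 2:
        return np.array([a.coord for a in res.atoms]).mean(axis=0)
    return res.atom(parts[2]).coord.copy()


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    ref: Sequence[Sequence[float]] | np.ndarray,
    mobile: Sequence[Sequence[float]] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``ref`` (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps mobile points onto the reference in
    the least-squares sense.  The rotation is proper (det = +1).

    Raises ``ValueError`` for mismatched lengths, fewer than three points, or
    degenerate (collinear/coincident) geometry.
    """
    P = np.asarray(ref, dtype=float)
    Q = np.asarray(mobile, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point lists must both be (n, 3) and equal length; got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 point pairs are required")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    scale = max(np.linalg.norm(P0), np.linalg.norm(Q0))
    if scale == 0 or S[1] <= 1e-10 * max(S[0], 1e-30):
        raise ValueError("degenerate geometry: points are collinear or coincident")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    diff = (Q0 @ R.T) - P0
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return R, t, rmsd


def superpose_chains(
    struct_ref: Structure,
    chain_ref: str,
    struct_mob: Structure,
    chain_mob: str,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Superpose one chain onto another via sequence-aligned Cα pairs.

    The pairing comes from a global pairwise alignment of the two chain
    sequences (BLOSUM62, gap open 10 / extend 0.5); gapped columns and
    residues lacking a Cα are excluded.  Returns
    ``(rotation, translation, rmsd, n_pairs)``.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    seq_r, res_r = struct_ref.chain_sequence(chain_ref)
    seq_m, res_m = struct_mob.chain_sequence(chain_mob)
    if not seq_r or not seq_m:
        raise StructureError("both chains must contain standard residues")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_r, seq_m)[0]
    ref_pts, mob_pts = [], []
    for (r0, r1), (m0, m1) in zip(*aln.aligned):
        for i, j in zip(range(r0, r1), range(m0, m1)):
            if res_r[i].has_atom("CA") and res_m[j].has_atom("CA"):
                ref_pts.append(res_r[i].atom("CA").coord)
                mob_pts.append(res_m[j].atom("CA").coord)
    if len(ref_pts) < 3:
        raise StructureError("fewer than 3 aligned Cα pairs")
    R, t, rmsd = kabsch_superpose(np.array(ref_pts), np.array(mob_pts))
    return R, t, rmsd, len(ref_pts)
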