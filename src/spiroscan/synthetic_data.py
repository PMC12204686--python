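"""Synthetic fixtures with machine-readable ground truth.

Every analysis stage in this package can be exercised without downloading
deposited structures: this module builds small multimeric structures with
designed inter-chain salt bridges and hydrogen bonds, pseudo-atom "phantom"
tubes enclosing a channel of known centerline and radius (optionally with a
carved solvent window), ligand trajectories with programmed escape frames
and hydrogen-bond occupancy, toy alignments with programmed per-column
conservation, and two-group length samples from stated distributions.

The fixtures mimic the *statistical and geometric* structure the analyses
assume — interface contact geometry, an enclosed tubular cavity, escape
hazards — not the AdhE fold or sequence itself.  Each generator is a pure
function of its parameters and seed, and each verifies its own ground truth
by brute force before returning it (a designed contact that is not actually
the closest compliant pair, or an accidental extra contact, raises).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .composition_conservation import AA_ALPHABET, MSA
from .contact_networks import (
    SALT_BRIDGE_ACIDIC,
    SALT_BRIDGE_BASIC,
    _SC_ACCEPTORS,
    _SC_DONORS,
)
from .structure_model import Atom, Residue, Structure, VDW_RADII
from .trajectory_channeling import LigandTrajectory
from .ultrastructure_stats import LengthDataset

__all__ = [
    "FixtureTruth",
    "make_toy_multimer",
    "make_channel_phantom",
    "make_synthetic_trajectories",
    "make_toy_msa",
    "make_length_samples",
    "straight_centerline",
    "sine_centerline",
]

CARBON_R = VDW_RADII["C"]  # phantom pseudo-atoms are uniform carbons


@dataclass
class FixtureTruth:
    kind: str
    parameters: dict
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Toy multimer with designed inter-chain contacts
# ---------------------------------------------------------------------------

_SLOT_SPACING = 6.0   # Å between residue slots along the chain axis
_SB_DIST = 3.7        # designed N···O salt-bridge distance (outside h-bond range)
_HB_DIST = 2.9        # designed donor···acceptor hydrogen-bond distance


def _residue(chain: str, number: int, name: str, atoms_spec, serial_start: int,
             hetero: bool = False) -> tuple[Residue, int]:
    res = Residue(chain_id=chain, number=number, insertion_code="", name=name)
    serial = serial_start
    for atom_name, element, coord in atoms_spec:
        res.atoms.append(Atom(serial=serial, name=atom_name, element=element,
                              coord=np.asarray(coord, float),
                              vdw_radius=VDW_RADII[element], is_hetero=hetero))
        serial += 1
    return res, serial


def _brute_force_contacts(structure: Structure, group_a, group_b):
    """Independent all-pairs scan for salt bridges and hydrogen bonds.

    Deliberately dumb (no spatial index, plain double loops) so it can serve
    as the generator's internal check on its own designed truth.
    """
    def atoms_of(chains, table, backbone=()):
        out = []
        for res in structure.residues(chains):
            names = set(table.get(res.name, ())) | set(backbone)
            for a in res.atoms:
                if a.name in names:
                    out.append((res, a))
        return out

    sb, hb = set(), set()
    for ga, gb, flip in ((group_a, group_b, False), (group_b, group_a, True)):
        basics = atoms_of(ga, SALT_BRIDGE_BASIC)
        acidics = atoms_of(gb, SALT_BRIDGE_ACIDIC)
        for res_p, ap in basics:
            for res_n, an in acidics:
                if np.linalg.norm(ap.coord - an.coord) <= 4.0:
                    pair = (res_n.id, res_p.id) if flip else (res_p.id, res_n.id)
                    sb.add(pair)
        donors = atoms_of(ga, _SC_DONORS, backbone=("N",))
        acceptors = atoms_of(gb, _SC_ACCEPTORS, backbone=("O", "OXT"))
        for res_d, ad in donors:
            for res_ac, aa in acceptors:
                if np.linalg.norm(ad.coord - aa.coord) <= 3.5:
                    pair = (res_ac.id, res_d.id) if flip else (res_d.id, res_ac.id)
                    hb.add(pair)
    return sb, hb


def make_toy_multimer(
    seed: int,
    n_salt_bridges: int = 2,
    n_hbonds: int = 3,
    separation: float = 12.0,
) -> tuple[Structure, FixtureTruth]:
    """Two-chain structure with exactly the requested inter-chain contacts.

    Chains A and B run parallel along x, ``separation`` Å apart.  Designed
    salt bridges are Lys NZ ... Asp OD1 at 3.7 Å (inside the 4.0 Å salt
    bridge cutoff, outside the 3.5 Å H-bond cutoff); designed hydrogen bonds
    are Ser OG ... Asn OD1 at 2.9 Å.  Filler alanines pad both ends.  The
    truth is re-verified by an internal brute-force scan; any accidental
    extra contact raises.
    """
    if n_salt_bridges < 0 or n_hbonds < 0:
        raise ValueError("contact counts must be >= 0")
    if separation < 10.0:
        raise ValueError(
            f"separation {separation} Å is infeasible: designed side chains would "
            "collide with the partner backbone (need >= 10 Å)")
    rng = np.random.default_rng(seed)
    n_designed = n_salt_bridges + n_hbonds
    n_slots = n_designed + 2  # filler at both ends
    kinds = ["sb"] * n_salt_bridges + ["hb"] * n_hbonds
    order = rng.permutation(n_designed)
    slot_kind = {1 + i: kinds[order[i]] for i in range(n_designed)}

    mid = separation / 2.0
    structure = Structure(id=f"toy_multimer_seed{seed}")
    serial = 1
    sb_truth, hb_truth = [], []
    for chain, y0, toward in (("A", 0.0, +1.0), ("B", separation, -1.0)):
        residues = []
        for slot in range(n_slots):
            x0 = slot * _SLOT_SPACING
            z = float(rng.uniform(-0.05, 0.05))  # rigid per-residue jitter
            kind = slot_kind.get(slot)
            backbone = [
                ("N", "N", (x0, y0, z)),
                ("CA", "C", (x0 + 1.5, y0, z)),
                ("C", "C", (x0 + 3.0, y0, z)),
                ("O", "O", (x0 + 3.0, y0 - toward * 1.2, z)),
            ]
            xt = x0 + 1.5  # side-chain tip x
            if kind == "sb" and chain == "A":
                spec = backbone + [("CB", "C", (xt, y0 + toward * 1.5, z)),
                                   ("NZ", "N", (xt, mid - _SB_DIST / 2, z))]
                name = "LYS"
            elif kind == "sb" and chain == "B":
                spec = backbone + [
                    ("CB", "C", (xt, y0 + toward * 1.5, z)),
                    ("CG", "C", (xt, mid + _SB_DIST / 2 + 1.3, z)),
                    ("OD1", "O", (xt, mid + _SB_DIST / 2, z)),
                    ("OD2", "O", (xt + 1.8, mid + _SB_DIST / 2 + 0.45, z)),
                ]
                name = "ASP"
            elif kind == "hb" and chain == "A":
                spec = backbone + [("CB", "C", (xt, y0 + toward * 1.5, z)),
                                   ("OG", "O", (xt, mid - _HB_DIST / 2, z))]
                name = "SER"
            elif kind == "hb" and chain == "B":
                spec = backbone + [
                    ("CB", "C", (xt, y0 + toward * 1.5, z)),
                    ("CG", "C", (xt, mid + _HB_DIST / 2 + 1.3, z)),
                    ("OD1", "O", (xt, mid + _HB_DIST / 2, z)),
                    ("ND2", "N", (xt + 1.8, mid + _HB_DIST / 2 + 1.0, z)),
                ]
                name = "ASN"
            else:
                spec = backbone + [("CB", "C", (xt, y0 + toward * 1.0, z))]
                name = "ALA"
            res, serial = _residue(chain, slot + 1, name, spec, serial)
            residues.append(res)
            if chain == "A" and kind == "sb":
                sb_truth.append((("A", slot + 1, ""), ("B", slot + 1, "")))
            if chain == "A" and kind == "hb":
                hb_truth.append((("A", slot + 1, ""), ("B", slot + 1, "")))
        structure.chains[chain] = residues

    sb_found, hb_found = _brute_force_contacts(structure, ["A"], ["B"])
    if sb_found != set(sb_truth) or hb_found != set(hb_truth):
        raise RuntimeError(
            "toy multimer self-check failed: designed contacts "
            f"sb={sorted(sb_truth)} hb={sorted(hb_truth)}, "
            f"found sb={sorted(sb_found)} hb={sorted(hb_found)}")
    truth = FixtureTruth(
        kind="toy_multimer",
        parameters={"seed": seed, "n_salt_bridges": n_salt_bridges,
                    "n_hbonds": n_hbonds, "separation": separation},
        truth={"salt_bridges": sorted(sb_truth), "hbonds": sorted(hb_truth)},
    )
    return structure, truth


# ---------------------------------------------------------------------------
# Channel phantoms
# ---------------------------------------------------------------------------

def straight_centerline(length: float = 30.0, spacing: float = 0.5) -> np.ndarray:
    n = int(round(length / spacing)) + 1
    x = np.linspace(0.0, length, n)
    return np.column_stack([x, np.zeros(n), np.zeros(n)])


def sine_centerline(length: float = 36.0, amplitude: float = 3.0,
                    period: float = 36.0, spacing: float = 0.5) -> np.ndarray:
    n = int(round(length / spacing)) * 4 + 1
    x = np.linspace(0.0, length, n)
    y = amplitude * np.sin(2 * np.pi * x / period)
    return np.column_stack([x, y, np.zeros(n)])


def _transport_frames(centerline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-transported normal/binormal along a polyline."""
    tangents = np.gradient(centerline, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.empty_like(tangents)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(tangents[0] @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n0 = np.cross(tangents[0], ref)
    normals[0] = n0 / np.linalg.norm(n0)
    for i in range(1, len(tangents)):
        n = normals[i - 1] - (normals[i - 1] @ tangents[i]) * tangents[i]
        normals[i] = n / np.linalg.norm(n)
    binormals = np.cross(tangents, normals)
    return normals, binormals


def _arc_lengths(centerline: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def make_channel_phantom(
    seed: int,
    centerline_spec: Optional[np.ndarray] = None,
    radius: float = 3.0,
    window: Optional[dict] = None,
    bulge: Optional[dict] = None,
    probe: float = 1.4,
    ring_spacing: float = 1.2,
    wall_atom_spacing: float = 1.5,
    with_decoy: bool = True,
    residue_name_cycle: Sequence[str] = ("ALA",),
    capped: bool = True,
) -> tuple[Structure, FixtureTruth]:
    """Pseudo-atom shell enclosing a tube of known centerline and lumen radius.

    Wall atoms are uniform carbons placed on rings of radius
    ``radius + CARBON_R`` so that the free clearance on the tube axis equals
    ``radius``; ring/atom spacing is dense enough that a 1.4 Å probe cannot
    leak between atoms.  ``window`` (``{"s": arc_fraction, "aperture": Å}``)
    carves a probe-admitting hole in the wall (atoms removed out to
    aperture + atom radius + probe) whose location is recorded in the truth.
    ``bulge`` (``{"s": arc_fraction, "extra": Å, "sigma": Å}``) widens the
    lumen by a Gaussian bump in local radius, recorded in the truth.  Both
    ends are capped by atom disks so a sealed phantom is entirely enclosed.
    One residue per ring (names cycled from ``residue_name_cycle``) in chain
    "T"; an optional far-away decoy blob occupies chain "D".
    """
    if radius <= probe:
        raise ValueError("lumen radius must exceed the probe radius")
    if centerline_spec is None:
        centerline_spec = straight_centerline()
    centerline = np.asarray(centerline_spec, dtype=float)
    if centerline.ndim != 2 or centerline.shape[1] != 3 or len(centerline) < 2:
        raise ValueError("centerline_spec must be an (n, 3) polyline")
    # self-intersection guard: non-neighbouring samples must stay apart
    arcs = _arc_lengths(centerline)
    for i in range(len(centerline)):
        for j in range(i + 1, len(centerline)):
            if arcs[j] - arcs[i] > 2.5 * radius and \
                    np.linalg.norm(centerline[j] - centerline[i]) < 2 * radius:
                raise ValueError("centerline self-intersects (tube would overlap)")

    rng = np.random.default_rng(seed)
    total = arcs[-1]
    n_rings = int(total / ring_spacing) + 1
    ring_s = np.linspace(0.0, total, n_rings)
    lumen = np.full(n_rings, float(radius))
    bulge_arc = None
    if bulge is not None:
        bulge_arc = float(bulge["s"]) * total
        extra = float(bulge.get("extra", 1.0))
        sigma = float(bulge.get("sigma", 2.5))
        lumen += extra * np.exp(-0.5 * ((ring_s - bulge_arc) / sigma) ** 2)
    ring_rs = lumen + CARBON_R
    ring_r = float(ring_rs.max())  # window offset / decoy placement scale
    # resample centerline at ring positions
    cx = np.column_stack([np.interp(ring_s, arcs, centerline[:, d]) for d in range(3)])
    dense_norm, dense_binorm = _transport_frames(centerline)
    nx = np.column_stack([np.interp(ring_s, arcs, dense_norm[:, d]) for d in range(3)])
    bx = np.column_stack([np.interp(ring_s, arcs, dense_binorm[:, d]) for d in range(3)])
    nx /= np.linalg.norm(nx, axis=1, keepdims=True)
    bx /= np.linalg.norm(bx, axis=1, keepdims=True)

    win_center = None
    win_removal = 0.0
    if window is not None:
        s_frac = float(window["s"])
        win_idx = int(np.clip(round(s_frac * (n_rings - 1)), 0, n_rings - 1))
        # "aperture" is the free radius the probe sees through the hole; wall
        # atoms must be cleared out to aperture + atom radius + probe radius
        # for the hole to actually admit the probe
        aperture = float(window.get("aperture", 1.5))
        win_removal = aperture + CARBON_R + probe
        win_center = cx[win_idx] + nx[win_idx] * ring_rs[win_idx]

    structure = Structure(id=f"phantom_seed{seed}")
    serial = 1
    wall_residues: list[Residue] = []
    phase = rng.uniform(0, 2 * np.pi)  # seed-dependent ring phase
    for i in range(n_rings):
        spec = []
        m = max(8, int(math.ceil(2 * np.pi * ring_rs[i] / wall_atom_spacing)))
        for k in range(m):
            theta = phase + 2 * np.pi * k / m
            pos = cx[i] + ring_rs[i] * (np.cos(theta) * nx[i] + np.sin(theta) * bx[i])
            if win_center is not None and np.linalg.norm(pos - win_center) <= win_removal:
                continue
            spec.append((f"C{k + 1}", "C", pos))
        if capped and i in (0, n_rings - 1):
            # cap disk: concentric rings shrinking to the axis
            rr = ring_rs[i] - wall_atom_spacing
            cap_k = m
            while rr > 0.3:
                mm = max(6, int(math.ceil(2 * np.pi * rr / wall_atom_spacing)))
                for k in range(mm):
                    theta = phase + 2 * np.pi * k / mm
                    pos = cx[i] + rr * (np.cos(theta) * nx[i] + np.sin(theta) * bx[i])
                    spec.append((f"C{cap_k + 1}", "C", pos))
                    cap_k += 1
                rr -= wall_atom_spacing
            spec.append((f"C{cap_k + 1}", "C", cx[i]))
        if not spec:
            continue
        name = residue_name_cycle[i % len(residue_name_cycle)]
        res, serial = _residue("T", i + 1, name, spec, serial)
        wall_residues.append(res)
    structure.chains["T"] = wall_residues

    decoy_ids = []
    if with_decoy:
        off = centerline.mean(axis=0) + np.array([0.0, 60.0, 0.0])
        spec = [(f"C{k + 1}", "C", off + rng.uniform(-2, 2, 3)) for k in range(8)]
        res, serial = _residue("D", 1, "GLY", spec, serial)
        structure.chains["D"] = [res]
        decoy_ids = [res.id]

    truth = FixtureTruth(
        kind="channel_phantom",
        parameters={"seed": seed, "radius": radius, "probe": probe,
                    "ring_spacing": ring_spacing, "window": window,
                    "bulge": bulge, "capped": capped},
        truth={
            "centerline": centerline.tolist(),
            "arc_length": float(total),
            "lumen_radius": radius,
            "lining_ids": sorted(r.id for r in wall_residues),
            "decoy_ids": decoy_ids,
            "window_center": None if win_center is None else win_center.tolist(),
            "window_arc_s": None if window is None else float(window["s"]) * float(total),
            "bulge_arc_s": bulge_arc,
        },
    )
    return structure, truth


# ---------------------------------------------------------------------------
# Synthetic ligand trajectories
# ---------------------------------------------------------------------------

def make_synthetic_trajectories(
    seed: int,
    n: int = 3,
    dt: float = 0.1,
    hazard_per_frame: float = 0.01,
    n_frames: int = 2000,
    occupancy_p: float = 0.3,
    escape_distance: float = 10.0,
    tube_length: float = 40.0,
    tube_radius: float = 3.0,
    sustain_margin: int = 5,
) -> tuple[list[LigandTrajectory], FixtureTruth]:
    """Ligand random walks inside a recorded tube with programmed escapes.

    At every frame from 1 on, the ligand escapes with probability
    ``hazard_per_frame``; after its escape frame it departs permanently
    beyond ``escape_distance`` from every protein atom.  An escape that
    would fall within ``sustain_margin`` frames of the end cannot be
    sustained and is generated as censored instead.  A designated
    donor/acceptor protein atom pair sits at hydrogen-bond distance with
    probability ``occupancy_p`` per frame.  The truth records, per
    replicate, the realized escape frame (or None) and the realized
    donor-acceptor contact fraction.
    """
    if not 0.0 <= hazard_per_frame <= 1.0:
        raise ValueError("hazard_per_frame must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ring_r = tube_radius + CARBON_R
    n_rings = int(tube_length / 2.0) + 1
    xs = np.linspace(0.0, tube_length, n_rings)
    wall = []
    for x in xs:
        for k in range(8):
            theta = 2 * np.pi * k / 8
            wall.append([x, ring_r * np.cos(theta), ring_r * np.sin(theta)])
    wall = np.asarray(wall)
    acceptor = np.array([0.0, -ring_r - 5.0, 0.0])
    centerline = np.column_stack([xs, np.zeros(n_rings), np.zeros(n_rings)])

    trajectories = []
    rep_truth = []
    for _ in range(n):
        # programmed escape frame: first Bernoulli success, frames 1..
        if hazard_per_frame > 0:
            e = int(rng.geometric(hazard_per_frame))
        else:
            e = n_frames + 1
        escaped = e <= n_frames - sustain_margin
        esc_frame = e if escaped else None

        lig = np.empty((n_frames, 1, 3))
        s = tube_length / 2.0
        radial = np.zeros(2)
        max_axis_dist = 0.0
        for f in range(n_frames):
            if esc_frame is not None and f >= esc_frame:
                lig[f, 0] = [tube_length / 2.0,
                             ring_r + 15.0 + 0.5 * (f - esc_frame), 0.0]
                continue
            s = float(np.clip(s + rng.normal(0, 0.8), 2.0, tube_length - 2.0))
            radial = radial + rng.normal(0, 0.4, 2)
            rnorm = np.linalg.norm(radial)
            rmax = 0.8 * tube_radius
            if rnorm > rmax:
                radial *= rmax / rnorm
            lig[f, 0] = [s, radial[0], radial[1]]
            max_axis_dist = max(max_axis_dist, float(np.linalg.norm(radial)))

        contact = rng.random(n_frames) < occupancy_p
        donor = np.empty((n_frames, 3))
        donor[:] = acceptor
        donor[:, 0] += np.where(contact, 2.9, 6.0)

        prot = np.empty((n_frames, len(wall) + 2, 3))
        prot[:, : len(wall), :] = wall[None, :, :]
        prot[:, len(wall), :] = acceptor[None, :]
        prot[:, len(wall) + 1, :] = donor

        traj = LigandTrajectory(
            dt=dt,
            ligand_coords=lig,
            protein_coords=prot,
            ligand_labels=["ACD:C1"],
            protein_labels=[f"TUB:C{i + 1}" for i in range(len(wall))] + ["ACC:O1", "DON:N1"],
        )
        # self-check: the programmed escape must be the first sustained
        # excursion of the realized geometry
        d = traj.min_distance_series()
        away = d > escape_distance
        if esc_frame is not None:
            if away[:esc_frame].any() or not away[esc_frame:].all():
                raise RuntimeError("trajectory self-check failed: escape not clean")
        elif away.any():
            raise RuntimeError("trajectory self-check failed: censored run leaves the tube")
        trajectories.append(traj)
        rep_truth.append({
            "escape_frame": esc_frame,
            "censored": esc_frame is None,
            "residence_ns": dt * (esc_frame if esc_frame is not None else n_frames),
            "occupancy_fraction": float(contact.mean()),
            "max_centerline_distance": max_axis_dist,
        })

    truth = FixtureTruth(
        kind="synthetic_trajectories",
        parameters={"seed": seed, "n": n, "dt": dt, "hazard_per_frame": hazard_per_frame,
                    "n_frames": n_frames, "occupancy_p": occupancy_p,
                    "escape_distance": escape_distance, "sustain_margin": sustain_margin,
                    "tube_length": tube_length, "tube_radius": tube_radius},
        truth={
            "replicates": rep_truth,
            "centerline": centerline.tolist(),
            "donor_index": len(wall) + 1,
            "acceptor_index": len(wall),
        },
    )
    return trajectories, truth


# ---------------------------------------------------------------------------
# Toy alignments
# ---------------------------------------------------------------------------

def make_toy_msa(
    seed: int,
    n_rows: int = 10,
    length: int = 40,
    conservation_profile: Optional[Sequence[float]] = None,
) -> tuple[MSA, FixtureTruth]:
    """Alignment whose per-column conservation hits programmed targets.

    For column ``c`` with target ``p``, exactly ``max(1, round(p * n_rows))``
    rows (always including the reference) carry the reference residue; the
    remaining rows carry a different residue.  The truth records the realized
    conservation of every column.
    """
    if conservation_profile is None:
        conservation_profile = [1.0] * length
    profile = [float(p) for p in conservation_profile]
    if len(profile) != length:
        raise ValueError("conservation_profile length must equal alignment length")
    if any(not 0.0 <= p <= 1.0 for p in profile):
        raise ValueError("conservation targets must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    aas = list(AA_ALPHABET)
    cols = []
    realized = []
    for p in profile:
        ref_aa = aas[rng.integers(len(aas))]
        k = max(1, int(round(p * n_rows)))
        matching = {0}
        if k > 1:
            others = 1 + rng.permutation(n_rows - 1)[: k - 1]
            matching.update(int(i) for i in others)
        col = []
        for r in range(n_rows):
            if r in matching:
                col.append(ref_aa)
            else:
                alt = aas[rng.integers(len(aas))]
                while alt == ref_aa:
                    alt = aas[rng.integers(len(aas))]
                col.append(alt)
        cols.append(col)
        realized.append(100.0 * k / n_rows)
    rows = ["".join(cols[c][r] for c in range(length)) for r in range(n_rows)]
    msa = MSA(names=[f"seq{r}" for r in range(n_rows)], rows=rows, ref_index=0)
    truth = FixtureTruth(
        kind="toy_msa",
        parameters={"seed": seed, "n_rows": n_rows, "length": length,
                    "conservation_profile": profile},
        truth={"realized_conservation_pct": realized},
    )
    return msa, truth


# ---------------------------------------------------------------------------
# Length samples
# ---------------------------------------------------------------------------

def make_length_samples(
    seed: int,
    group_params: Optional[dict[str, tuple[float, float]]] = None,
    n: int = 1250,
) -> tuple[LengthDataset, FixtureTruth]:
    """Positive-truncated normal length samples for two (or more) groups.

    Defaults emulate negative-stain spirosome length measurements at the
    scale of the published experiment: 1250 measurements per group, with the
    exogenously expressed population ~20 nm shorter on average than the
    native one.
    """
    if group_params is None:
        group_params = {"native": (80.0, 25.0), "exogenous": (60.0, 25.0)}
    if n < 1:
        raise ValueError("n must be >= 1")
    from scipy.stats import truncnorm
    rng = np.random.default_rng(seed)
    groups = {}
    realized = {}
    for label, (mean, sd) in group_params.items():
        if sd <= 0:
            raise ValueError(f"group {label!r}: sd must be > 0")
        a = (0.0 - mean) / sd
        vals = truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
        groups[label] = vals
        realized[label] = {"mean": float(vals.mean()),
                           "sd": float(vals.std(ddof=1)) if n > 1 else 0.0,
                           "median": float(np.median(vals)), "n": n}
    data = LengthDataset(groups=groups)
    truth = FixtureTruth(
        kind="length_samples",
        parameters={"seed": seed, "n": n,
                    "group_params": {k: list(v) for k, v in group_params.items()}},
        truth={"realized": realized},
    )
    return data, truth
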