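"""Amino-acid composition, channel enrichment, and sequence conservation.

The channel that funnels acetaldehyde between the ALDH and ADH active sites
of the AdhE spirosome has a distinctive chemistry: almost no lysine (whose
primary amine would cross-link with aldehydes), a surplus of histidine, and
— in extended spirosomes — of phenylalanine.  This module quantifies such
signals: 20-symbol composition profiles, Jeffreys-smoothed log2-fold
enrichment of a channel lining versus the whole protein, MSA column
conservation against a reference row, pairwise global identity, motif
scanning (``GxGxxG``-style patterns) and residue-set homology across a
species correspondence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import Align, AlignIO
from Bio.Align import substitution_matrices

from .structure_model import Structure, StructureError, THREE_TO_ONE

__all__ = [
    "AA_ALPHABET",
    "CompositionProfile",
    "EnrichmentTable",
    "MSA",
    "aa_composition",
    "composition_from_sequence",
    "log2_enrichment",
    "read_msa",
    "pairwise_identity",
    "make_position_mapping",
    "column_conservation",
    "motif_scan",
    "set_homology",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# coarse physicochemical classes used for the similarity variant of
# residue-set homology (reported alongside strict identity)
_SIMILARITY_CLASSES = [
    set("AVLIMC"), set("FWY"), set("ST"), set("NQ"), set("DE"), set("KRH"),
    set("G"), set("P"),
]


@dataclass
class CompositionProfile:
    counts: dict[str, int]
    n_nonstandard: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {aa: 0.0 for aa in AA_ALPHABET}
        return {aa: self.counts.get(aa, 0) / t for aa in AA_ALPHABET}


@dataclass
class EnrichmentTable:
    log2fc: dict[str, float]
    smoothing_alpha: float


@dataclass
class MSA:
    names: list[str]
    rows: list[str]
    ref_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        L = len(self.rows[0])
        for name, row in zip(self.names, self.rows):
            if len(row) != L:
                raise ValueError(f"ragged alignment: row {name!r} has length {len(row)}, expected {L}")
        if not any(c != "-" for c in self.rows[self.ref_index]):
            raise ValueError("reference row is all gaps")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def set_reference(self, name: str) -> None:
        try:
            self.ref_index = self.names.index(name)
        except ValueError as exc:
            raise KeyError(f"no row named {name!r} in alignment") from exc


# ---------------------------------------------------------------------------
# Composition and enrichment
# ---------------------------------------------------------------------------

def aa_composition(
    residue_ids: Iterable[tuple[str, int, str]],
    structure: Structure,
) -> CompositionProfile:
    """Composition profile of a residue-id set within a structure.

    Non-standard residues are excluded from the counts and tallied in
    ``n_nonstandard``.
    """
    ids = list(residue_ids)
    if not ids:
        raise StructureError("residue set is empty")
    counts = {aa: 0 for aa in AA_ALPHABET}
    n_nonstd = 0
    for cid, num, icode in ids:
        res = structure.residue(cid, num, icode)
        one = THREE_TO_ONE.get(res.name)
        if one is None:
            n_nonstd += 1
        else:
            counts[one] += 1
    return CompositionProfile(counts=counts, n_nonstandard=n_nonstd)


def composition_from_sequence(sequence: str) -> CompositionProfile:
    counts = {aa: 0 for aa in AA_ALPHABET}
    n_nonstd = 0
    for c in sequence.upper():
        if c in counts:
            counts[c] += 1
        else:
            n_nonstd += 1
    return CompositionProfile(counts=counts, n_nonstandard=n_nonstd)


def log2_enrichment(
    channel: CompositionProfile,
    protein: CompositionProfile,
    alpha: float = 0.5,
) -> EnrichmentTable:
    """Jeffreys-smoothed log2-fold enrichment of channel vs whole protein.

    log2fc[a] = log2( ((c_a + alpha)/(C + 20 alpha)) / ((p_a + alpha)/(P + 20 alpha)) )

    alpha > 0 keeps amino acids absent from the channel (e.g. the single
    lysine case) finite and strongly negative instead of -inf.
    """
    if alpha <= 0:
        raise ValueError("smoothing alpha must be > 0")
    if protein.total == 0:
        raise StructureError("protein profile has zero total count")
    C = channel.total + 20 * alpha
    P = protein.total + 20 * alpha
    log2fc = {}
    for aa in AA_ALPHABET:
        fc = ((channel.counts.get(aa, 0) + alpha) / C) / ((protein.counts.get(aa, 0) + alpha) / P)
        log2fc[aa] = math.log2(fc)
    return EnrichmentTable(log2fc=log2fc, smoothing_alpha=alpha)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_msa(path: str | Path, fmt: Optional[str] = None, ref_name: Optional[str] = None) -> MSA:
    """Read a FASTA or Clustal multiple alignment."""
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in (".aln", ".clustal", ".clu") else "fasta"
    fmt = fmt.lower()
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported MSA format {fmt!r}")
    if fmt == "fasta":
        # parse leniently, then validate row lengths ourselves so a ragged
        # alignment error can name the offending row
        from Bio import SeqIO
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        records = list(AlignIO.read(str(path), "clustal"))
    if not records:
        raise ValueError(f"{path}: no sequences found")
    names = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    msa = MSA(names=names, rows=rows)
    if ref_name is not None:
        msa.set_reference(ref_name)
    return msa


def _aligner(matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _validate_seq(seq: str, label: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = sorted(set(seq) - set(AA_ALPHABET))
    if bad:
        raise ValueError(f"{label}: non-amino-acid characters {bad}")
    return seq


def _aligned_columns(aln) -> list[tuple[Optional[int], Optional[int]]]:
    """Per-column (i, j) indices of a pairwise alignment; None marks a gap."""
    cols: list[tuple[Optional[int], Optional[int]]] = []
    a_blocks, b_blocks = aln.aligned
    pa = pb = 0
    for (a0, a1), (b0, b1) in zip(a_blocks, b_blocks):
        while pa < a0:
            cols.append((pa, None))
            pa += 1
        while pb < b0:
            cols.append((None, pb))
            pb += 1
        for i, j in zip(range(a0, a1), range(b0, b1)):
            cols.append((i, j))
        pa, pb = a1, b1
    la = len(aln.sequences[0])
    lb = len(aln.sequences[1])
    while pa < la:
        cols.append((pa, None))
        pa += 1
    while pb < lb:
        cols.append((None, pb))
        pb += 1
    return cols


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Global (Needleman-Wunsch) percent identity of two protein sequences.

    Identity = identical columns / aligned columns, excluding terminal-gap
    columns from the denominator, as percent.
    """
    seq_a = _validate_seq(seq_a, "seq_a")
    seq_b = _validate_seq(seq_b, "seq_b")
    aln = _aligner(matrix, gap_open, gap_extend).align(seq_a, seq_b)[0]
    cols = _aligned_columns(aln)
    # trim terminal gap columns
    first = 0
    while first < len(cols) and (cols[first][0] is None or cols[first][1] is None):
        first += 1
    last = len(cols)
    while last > first and (cols[last - 1][0] is None or cols[last - 1][1] is None):
        last -= 1
    core = cols[first:last]
    if not core:
        return 0.0
    ident = sum(
        1 for i, j in core
        if i is not None and j is not None and seq_a[i] == seq_b[j]
    )
    return 100.0 * ident / len(core)


def make_position_mapping(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> dict[int, int]:
    """0-based position correspondence a->b from a global pairwise alignment."""
    seq_a = _validate_seq(seq_a, "seq_a")
    seq_b = _validate_seq(seq_b, "seq_b")
    aln = _aligner(matrix, gap_open, gap_extend).align(seq_a, seq_b)[0]
    mapping: dict[int, int] = {}
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            mapping[i] = j
    return mapping


def column_conservation(msa: MSA) -> dict[int, float]:
    """Percent conservation per reference position (1-based, gaps skipped).

    For each non-gap column of the reference row, the percent of rows
    (reference included) whose residue matches the reference residue; a gap
    in another row counts as a mismatch.
    """
    ref = msa.rows[msa.ref_index]
    n = len(msa.rows)
    out: dict[int, float] = {}
    pos = 0
    for col, ref_char in enumerate(ref):
        if ref_char == "-":
            continue
        pos += 1
        matches = sum(1 for row in msa.rows if row[col] == ref_char)
        out[pos] = 100.0 * matches / n
    return out


def motif_scan(sequence: str, pattern: str) -> list[int]:
    """1-based start positions of all (possibly overlapping) motif matches.

    ``x`` (either case) in the pattern matches any residue; other characters
    match literally.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    seq = sequence.upper()
    pat = pattern.upper()
    hits = []
    m = len(pat)
    for start in range(len(seq) - m + 1):
        if all(p == "X" or p == seq[start + k] for k, p in enumerate(pat)):
            hits.append(start + 1)
    return hits


def set_homology(
    set_a: Iterable[int],
    set_b: Iterable[int],
    seq_a: str,
    seq_b: str,
    mapping: Optional[Mapping[int, int]] = None,
) -> dict[str, float | int]:
    """Cross-species identity of a residue set under a position correspondence.

    ``set_a``/``set_b`` are 0-based positions into ``seq_a``/``seq_b`` (e.g.
    channel-lining positions in two species).  ``mapping`` maps a-positions
    to b-positions; when omitted it is built from a global pairwise
    alignment.  The homology percent is the fraction of channel positions
    (union over both species, expressed in a-coordinates where mapped) whose
    residues are identical across the correspondence; positions with no
    counterpart count as non-identical and are reported.
    """
    A, B = set(set_a), set(set_b)
    if not A or not B:
        raise ValueError("residue sets must be non-empty")
    if mapping is None:
        mapping = make_position_mapping(seq_a, seq_b)
    inv = {j: i for i, j in mapping.items()}
    # channel positions in a-coordinates: a-side positions plus mapped b-side ones
    positions = set(A)
    unmapped_b = 0
    for j in B:
        if j in inv:
            positions.add(inv[j])
        else:
            unmapped_b += 1
    identical = 0
    similar = 0
    unmapped_a = 0
    for i in sorted(positions):
        j = mapping.get(i)
        if j is None:
            unmapped_a += 1
            continue
        a_res, b_res = seq_a[i], seq_b[j]
        if a_res == b_res:
            identical += 1
            similar += 1
        elif any(a_res in cls and b_res in cls for cls in _SIMILARITY_CLASSES):
            similar += 1
    denom = len(positions) + unmapped_b
    return {
        "identity_pct": 100.0 * identical / denom,
        "similarity_pct": 100.0 * similar / denom,
        "n_positions": denom,
        "n_unmapped": unmapped_a + unmapped_b,
    }
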