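#!/usr/bin/env python
"""Fetch the deposited inputs needed by the deposited-structure tests.

Run once on a machine with network access:

    python scripts/fetch_inputs.py

Downloads the mmCIF coordinate files analysed by the pipeline into
``data/structures/`` and extracts the AdhE sequences (from the extended
C. thermocellum deposit and the compact E. coli deposit) into
``data/sequences/``.  The files are not redistributed with the package.
"""

from __future__ import annotations

import gzip
import sys
import urllib.request
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
STRUCTS = ROOT / "data" / "structures"
SEQS = ROOT / "data" / "sequences"

PDB_IDS = ["8UHW", "6AHC", "5JFM", "7BVP", "6TQH", "6TQM"]
SEQUENCE_SOURCES = {
    # species sequences taken from the deposited coordinate entities
    "CtAdhE": "8UHW",
    "EcAdhE": "6AHC",
}


def fetch_structure(pdb_id: str, dest: Path) -> None:
    url = f"https://files.rcsb.org/download/{pdb_id}.cif.gz"
    print(f"fetching {url}")
    with urllib.request.urlopen(url, timeout=120) as resp:
        payload = gzip.decompress(resp.read())
    dest.write_bytes(payload)
    print(f"  wrote {dest} ({len(payload) // 1024} kB)")


def extract_sequence(pdb_path: Path, name: str, dest: Path) -> None:
    from spiroscan.structure_model import load_structure

    st = load_structure(pdb_path)
    chain = st.chain_ids[0]
    seq, _ = st.chain_sequence(chain)
    dest.write_text(f">{name} chain {chain} of {pdb_path.stem}\n{seq}\n")
    print(f"  wrote {dest} ({len(seq)} aa)")


def main() -> int:
    STRUCTS.mkdir(parents=True, exist_ok=True)
    SEQS.mkdir(parents=True, exist_ok=True)
    for pdb_id in PDB_IDS:
        dest = STRUCTS / f"{pdb_id}.cif"
        if dest.exists():
            print(f"{dest} already present, skipping")
            continue
        try:
            fetch_structure(pdb_id, dest)
        except Exception as exc:  # noqa: BLE001
            print(f"  FAILED for {pdb_id}: {exc}", file=sys.stderr)
    for name, pdb_id in SEQUENCE_SOURCES.items():
        src = STRUCTS / f"{pdb_id}.cif"
        dest = SEQS / f"{name}.fasta"
        if not src.exists():
            print(f"cannot extract {name}: {src} missing", file=sys.stderr)
            continue
        if not dest.exists():
            extract_sequence(src, name, dest)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
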