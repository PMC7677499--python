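"""Constant tables: van der Waals radii and the Kyte–Doolittle hydropathy scale.

Both tables ship with defaults and can be overridden from flat ``key value``
config files (one entry per line, ``#`` comments allowed).  Every analysis
report records a fingerprint of the radii table actually used, so results are
traceable to the table.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import gemmi

#: Per-element van der Waals radii in Å.  Elements missing from the table fall
#: back to ``DEFAULT_VDW_RADIUS`` unless the caller disables defaults.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.50,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
}

DEFAULT_VDW_RADIUS: float = 1.80

#: Kyte–Doolittle hydropathy indices for the 20 standard amino acids
#: (positive = hydrophobic).
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5,
    "VAL": 4.2,
    "LEU": 3.8,
    "PHE": 2.8,
    "CYS": 2.5,
    "MET": 1.9,
    "ALA": 1.8,
    "GLY": -0.4,
    "THR": -0.7,
    "SER": -0.8,
    "TRP": -0.9,
    "TYR": -1.3,
    "PRO": -1.6,
    "HIS": -3.2,
    "GLU": -3.5,
    "GLN": -3.5,
    "ASP": -3.5,
    "ASN": -3.5,
    "LYS": -3.9,
    "ARG": -4.5,
}

STANDARD_RESIDUES: frozenset[str] = frozenset(KYTE_DOOLITTLE)


def load_table(path: str | Path) -> dict[str, float]:
    """Load a flat ``key value`` table (element→Å or residue→index)."""
    table: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed table line: {raw!r}")
        table[parts[0].upper()] = float(parts[1])
    return table


def table_fingerprint(table: Mapping[str, float]) -> str:
    """Short stable hash of a table, recorded in result fingerprints."""
    blob = ";".join(f"{k}={table[k]:.6g}" for k in sorted(table))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def element_mass(symbol: str) -> float:
    """Atomic mass (u) of an element symbol, via gemmi's element table."""
    el = gemmi.Element(symbol)
    if el.name == "X" and symbol.upper() not in ("X",):
        raise KeyError(f"unknown element symbol: {symbol!r}")
    return float(el.weight)


def kd_index(residue_name: str) -> float:
    """Kyte–Doolittle hydropathy index of a standard residue (case-insensitive).

    Raises ``KeyError`` for non-standard residues; callers that want the
    exclude-with-warning fallback handle it at the shell-summation level.
    """
    name = residue_name.strip().upper()
    try:
        return KYTE_DOOLITTLE[name]
    except KeyError:
        raise KeyError(
            f"no hydropathy index for non-standard residue {residue_name!r}"
        ) from None
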