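"""Optional PDB-format dumps of grid results for visualization."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cavity import CavityResult
from .surface import SurfaceMetrics


def _pdb_pseudo_atoms(coords: np.ndarray, occ: np.ndarray, b: np.ndarray) -> str:
    lines = []
    for i, (xyz, o, bf) in enumerate(zip(coords, occ, b), start=1):
        serial = i % 100000
        lines.append(
            f"HETATM{serial:5d}  O   DUM X{(i % 10000):4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{min(o, 99.0):6.2f}{bf:6.2f}"
            f"           O"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def dump_cavity_pdb(result: CavityResult, path: str | Path, stride: int = 1) -> None:
    """Write cavity grid points as pseudo-atoms (occupancy = chamber label)."""
    idx = np.argwhere(result.labels > 0)[::stride]
    labels = result.labels[result.labels > 0][::stride]
    coords = result.grid.world_coords(idx)
    Path(path).write_text(
        _pdb_pseudo_atoms(coords, labels.astype(float), np.zeros(len(idx)))
    )


def dump_surface_pdb(metrics: SurfaceMetrics, path: str | Path) -> None:
    """Write surface points as pseudo-atoms (B-factor 1 = contact, 0 = cap)."""
    if metrics.grid is None:
        raise ValueError("surface metrics carry no grid")
    coords = metrics.grid.world_coords(metrics.surface_points)
    Path(path).write_text(
        _pdb_pseudo_atoms(
            coords,
            np.ones(len(coords)),
            metrics.contact.astype(float),
        )
    )
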