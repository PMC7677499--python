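"""PDB structure reading, sanitization, and radius/hydropathy assignment.

The cavity algorithms operate on plain protein-atom geometry: coordinates,
van der Waals radii, masses, and the residue identity of every atom.  This
module reduces an arbitrary PDB file to that, following fixed sanitization
rules:

* first MODEL only;
* ATOM records of the 20 standard amino acids (waters, ligands, nucleic acids
  and other HETATM content removed); non-standard residues such as MSE are
  dropped with a warning unless ``keep_nonstandard`` is set;
* alternate locations reduced to a single conformer (blank or 'A' altloc,
  first occurrence wins);
* hydrogens are used when present but never added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .tables import (
    DEFAULT_VDW_RADIUS,
    STANDARD_RESIDUES,
    VDW_RADII,
    element_mass,
    kd_index,
)

logger = logging.getLogger(__name__)


class StructureError(ValueError):
    """Raised for unreadable files, missing chains, or empty structures."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) Å
    vdw_radius: float  # Å
    mass: float  # u
    residue_name: str
    residue_seq: int
    icode: str
    chain_id: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")


@dataclass
class Residue:
    name: str
    seq: int
    icode: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def q(self) -> float | None:
        """Kyte–Doolittle hydropathy index, or None for non-standard names."""
        try:
            return kd_index(self.name)
        except KeyError:
            return None

    def center_of_mass(self) -> np.ndarray:
        m = np.array([a.mass for a in self.atoms])
        x = np.array([a.coords for a in self.atoms])
        return (m[:, None] * x).sum(axis=0) / m.sum()

    def c_alpha(self) -> np.ndarray | None:
        for a in self.atoms:
            if a.name.strip() == "CA" and a.element == "C":
                return a.coords
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq, self.icode)


@dataclass
class Structure:
    """A sanitized protein structure (possibly multi-chain)."""

    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def __len__(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        """(N, 3) array of atom coordinates in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def atom_residue_index(self) -> np.ndarray:
        """For each atom (flattened order), the index of its residue."""
        idx = np.empty(len(self), dtype=int)
        pos = 0
        for i, r in enumerate(self.residues):
            idx[pos : pos + len(r.atoms)] = i
            pos += len(r.atoms)
        return idx

    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure with replaced atom coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise ValueError("coordinate array shape mismatch")
        new_residues = []
        k = 0
        for r in self.residues:
            new_atoms = [replace(a, coords=coords[k + j].copy()) for j, a in enumerate(r.atoms)]
            k += len(r.atoms)
            new_residues.append(replace(r, atoms=new_atoms))
        return Structure(id=self.id, residues=new_residues)

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)


def _radius_for(element: str, table: Mapping[str, float], allow_default: bool) -> float:
    key = element.upper().capitalize() if len(element) > 1 else element.upper()
    for k in (element, element.upper(), key):
        if k in table:
            return table[k]
    if allow_default:
        return table.get("*", DEFAULT_VDW_RADIUS)
    raise StructureError(f"no van der Waals radius for element {element!r} and defaults disabled")


def read_structure(
    path: str | Path,
    chains: str | Sequence[str] | None = None,
    radii_table: Mapping[str, float] | None = None,
    keep_nonstandard: bool = False,
    allow_default_radius: bool = True,
) -> Structure:
    """Read a PDB (optionally gzipped) file and return a sanitized Structure.

    Parameters
    ----------
    chains
        Chain id or iterable of chain ids to retain; default keeps all chains.
    radii_table
        Element→Å mapping; defaults to the shipped Pauling-style table.
    keep_nonstandard
        Retain non-standard amino-acid residues (e.g. MSE) with element-based
        radii.  They never contribute to hydropathy sums.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on garbage
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    if chains is None:
        wanted = None
    elif isinstance(chains, str):
        wanted = {c.strip() for c in chains.split(",") if c.strip()}
    else:
        wanted = set(chains)

    table = dict(radii_table) if radii_table is not None else dict(VDW_RADII)

    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]  # first MODEL only

    available = [ch.name for ch in model]
    if wanted is not None:
        missing = wanted - set(available)
        if missing:
            raise StructureError(
                f"{path}: chain(s) {sorted(missing)} not found; available: {available}"
            )

    residues: list[Residue] = []
    n_nonstandard = 0
    serial = 0
    for chain in model:
        if wanted is not None and chain.name not in wanted:
            continue
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            is_standard = res.name.upper() in STANDARD_RESIDUES
            is_aa = is_standard or (info is not None and info.is_amino_acid())
            if not is_aa:
                continue  # water, ligand, nucleic acid, ...
            if not is_standard:
                n_nonstandard += 1
                if not keep_nonstandard:
                    continue
            out = Residue(
                name=res.name.upper(),
                seq=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                chain_id=chain.name,
            )
            seen_names: set[str] = set()
            for atom in res:
                alt = atom.altloc if atom.altloc not in ("\x00",) else ""
                if alt not in ("", "A"):
                    continue  # single conformer: blank or 'A' altloc
                if atom.name in seen_names:
                    continue  # first occurrence wins on duplicate altloc A
                seen_names.add(atom.name)
                serial += 1
                el = atom.element.name
                out.atoms.append(
                    Atom(
                        serial=serial,
                        name=atom.name,
                        element=el,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        vdw_radius=_radius_for(el, table, allow_default_radius),
                        mass=element_mass(el),
                        residue_name=out.name,
                        residue_seq=out.seq,
                        icode=out.icode,
                        chain_id=out.chain_id,
                    )
                )
            if out.atoms:
                residues.append(out)

    if n_nonstandard and not keep_nonstandard:
        logger.warning(
            "%s: excluded %d non-standard residue(s)", path.name, n_nonstandard
        )
    if not residues:
        raise StructureError(f"{path}: no protein atoms after sanitization")
    return Structure(id=path.stem, residues=residues)


def assign_radii(
    structure: Structure,
    radii_table: Mapping[str, float],
    allow_default: bool = True,
) -> Structure:
    """Return a copy of the structure with radii re-assigned from a table."""
    new_res = []
    for r in structure.residues:
        atoms = [
            replace(a, vdw_radius=_radius_for(a.element, radii_table, allow_default))
            for a in r.atoms
        ]
        new_res.append(replace(r, atoms=atoms))
    return Structure(id=structure.id, residues=new_res)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write the structure as a minimal single-model PDB file."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    chain_order: list[str] = []
    for res in structure.residues:
        chain = chain_map.get(res.chain_id)
        if chain is None:
            chain = gemmi.Chain(res.chain_id)
            chain_map[res.chain_id] = chain
            chain_order.append(res.chain_id)
        g_res = gemmi.Residue()
        g_res.name = res.name
        g_res.seqid = gemmi.SeqId(res.seq, res.icode or " ")
        g_res.het_flag = "A"
        for a in res.atoms:
            g_atom = gemmi.Atom()
            g_atom.name = a.name
            g_atom.element = gemmi.Element(a.element)
            g_atom.pos = gemmi.Position(*a.coords)
            g_atom.occ = 1.0
            g_atom.b_iso = 0.0
            g_res.add_atom(g_atom)
        chain.add_residue(g_res)
    for name in chain_order:
        model.add_chain(chain_map[name])
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
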