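"""Synthetic PDB structures with analytically known cavity properties.

Real survey structures have no exact ground truth, so the test bed is built
from pseudo-proteins: spherical shells of single-atom pseudo-residues placed
on a Fibonacci lattice, optionally with caps removed (open cups), axis bores,
two linked voids (dumbbells), hemisphere hydropathy labeling, or a ring of
chains that only jointly enclose a void.  Atom spacing on every shell is kept
below ``0.8 × 2 r_w`` so a water probe cannot leak between atoms where
closure is intended; construction fails loudly if the bound is violated.

Each generator returns ``(Structure, expected)`` where ``expected`` is a
machine-readable record of the analytic values and tolerances the fixture
guarantees (e.g. the sealed-shell cavity volume (4/3)π(R_s − r_atom)³, which
is the probe-center ball of radius R_s − r_atom − r_w dilated back by r_w).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, Residue, Structure
from .tables import element_mass

DEFAULT_PROBE_RADIUS = 1.42
LEAK_MARGIN = 0.8  # spacing bound factor: max NN distance ≤ 0.8 × 2 r_w


class FixtureError(ValueError):
    """Raised when requested geometry cannot guarantee its analytic contract."""


@dataclass
class FixtureSpec:
    kind: str
    params: dict
    seed: int = 0


def fibonacci_sphere(n: int) -> np.ndarray:
    """(n, 3) quasi-uniform unit vectors on the sphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _check_sealed(points: np.ndarray, r_w: float) -> float:
    """Max nearest-neighbor distance; error if above the leak bound."""
    if len(points) < 2:
        raise FixtureError("shell needs at least 2 atoms")
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    max_nn = float(d[:, 1].max())
    bound = LEAK_MARGIN * 2.0 * r_w
    if max_nn > bound:
        raise FixtureError(
            f"shell atom spacing {max_nn:.2f} Å exceeds leak bound {bound:.2f} Å; "
            "increase the atom count"
        )
    return max_nn


def _shell_atom_count(radius: float, r_w: float) -> int:
    """Atom count giving Fibonacci NN spacing safely below the leak bound."""
    target = LEAK_MARGIN * 2.0 * r_w * 0.8  # extra headroom below the bound
    return max(16, int(math.ceil((3.9 * radius / target) ** 2)))


def _build(
    points: np.ndarray,
    residue_names,
    chain_ids,
    atom_radius: float,
    structure_id: str,
) -> Structure:
    """One single-atom pseudo-residue per point."""
    mass = element_mass("C")
    residues: list[Residue] = []
    # group contiguously by chain for tidy PDB output
    order = np.argsort(np.asarray(chain_ids), kind="stable")
    seq_by_chain: dict[str, int] = {}
    for serial, k in enumerate(order, start=1):
        ch = chain_ids[k]
        seq_by_chain[ch] = seq_by_chain.get(ch, 0) + 1
        res = Residue(name=residue_names[k], seq=seq_by_chain[ch], icode="", chain_id=ch)
        res.atoms.append(
            Atom(
                serial=serial,
                name="C",
                element="C",
                coords=points[k],
                vdw_radius=atom_radius,
                mass=mass,
                residue_name=res.name,
                residue_seq=res.seq,
                icode="",
                chain_id=ch,
            )
        )
        residues.append(res)
    return Structure(id=structure_id, residues=residues)


def _sphere_points(
    radius: float,
    n_atoms: int | None,
    r_w: float,
    seed: int,
    jitter: float,
) -> np.ndarray:
    n = n_atoms if n_atoms is not None else _shell_atom_count(radius, r_w)
    pts = radius * fibonacci_sphere(n)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        offs = rng.normal(scale=jitter, size=pts.shape)
        pts = pts + offs
    return pts


def make_hollow_sphere(
    radius: float = 15.0,
    atom_radius: float = 1.7,
    n_atoms: int | None = None,
    residue_name: str = "GLY",
    r_w: float = DEFAULT_PROBE_RADIUS,
    seed: int = 0,
    jitter: float = 0.0,
) -> tuple[Structure, dict]:
    """Sealed spherical shell enclosing a void of analytic volume."""
    if radius <= atom_radius + 2.0 * r_w:
        raise FixtureError("shell radius too small to enclose a probe-accessible void")
    pts = _sphere_points(radius, n_atoms, r_w, seed, jitter)
    spacing = _check_sealed(pts, r_w)
    n = len(pts)
    st = _build(pts, [residue_name] * n, ["A"] * n, atom_radius, "hollow_sphere")
    inner = radius - atom_radius
    v_c = 4.0 / 3.0 * math.pi * inner**3 / 1000.0
    expected = {
        "kind": "hollow_sphere",
        "n_atoms": n,
        "max_nn_spacing": spacing,
        "v_c_nm3": v_c,
        "v_c_formula": "(4/3)*pi*(R_s - r_atom)^3",
        "v_c_tol_rel": 0.10,
        "s_min": 0.95,
        "w_abs_max": 0.05,
        "entrances": 0,
    }
    return st, expected


def make_open_cup(
    radius: float = 15.0,
    aperture_deg: float = 120.0,
    atom_radius: float = 1.7,
    n_atoms: int | None = None,
    residue_name: str = "GLY",
    r_w: float = DEFAULT_PROBE_RADIUS,
    seed: int = 0,
) -> tuple[Structure, dict]:
    """Spherical shell with a polar cap removed (opening toward +z).

    Larger apertures expose more of the void and drive the closure fraction
    s down toward the pocket regime.
    """
    if not 10.0 <= aperture_deg <= 180.0:
        raise FixtureError("aperture must be within 10°–180°")
    full = _sphere_points(radius, n_atoms, r_w, seed, 0.0)
    _check_sealed(full, r_w)  # the parent shell must be leak-tight
    theta = np.degrees(np.arccos(np.clip(full[:, 2] / radius, -1, 1)))
    pts = full[theta >= aperture_deg / 2.0]
    n = len(pts)
    st = _build(pts, [residue_name] * n, ["A"] * n, atom_radius, f"open_cup_{int(aperture_deg)}")
    expected = {
        "kind": "open_cup",
        "aperture_deg": aperture_deg,
        "n_atoms": n,
    }
    return st, expected


def make_bored_sphere(
    radius: float = 15.0,
    bore_diameter: float = 4.0,
    atom_radius: float = 1.7,
    n_atoms: int | None = None,
    residue_name: str = "GLY",
    r_w: float = DEFAULT_PROBE_RADIUS,
    seed: int = 0,
) -> tuple[Structure, dict]:
    """Sealed shell pierced by a straight z-axis bore of given clear diameter."""
    full = _sphere_points(radius, n_atoms, r_w, seed, 0.0)
    _check_sealed(full, r_w)
    rho = np.hypot(full[:, 0], full[:, 1])
    pts = full[rho >= bore_diameter / 2.0 + atom_radius]
    n = len(pts)
    st = _build(pts, [residue_name] * n, ["A"] * n, atom_radius, "bored_sphere")
    expected = {
        "kind": "bored_sphere",
        "bore_diameter": bore_diameter,
        "bore_admits_probe": bore_diameter > 2.0 * r_w,
        "n_atoms": n,
    }
    return st, expected


def make_dumbbell(
    r1: float = 12.0,
    r2: float = 8.0,
    separation: float | None = None,
    atom_radius: float = 1.7,
    r_w: float = DEFAULT_PROBE_RADIUS,
    residue_name: str = "GLY",
    seed: int = 0,
) -> tuple[Structure, dict]:
    """Two spherical voids along x: separate chambers, or one if merged.

    With ``separation ≥ r1 + r2`` (default r1 + r2 + 2 Å) the shells are
    disjoint and sealed → two chambers, V_C the larger void's volume.  With a
    smaller separation the shells overlap; atoms inside the other sphere are
    dropped, opening a circular passage whose clear radius is reported so the
    caller can make it wider than the probe.
    """
    if separation is None:
        separation = r1 + r2 + 2.0
    c1 = np.array([0.0, 0.0, 0.0])
    c2 = np.array([separation, 0.0, 0.0])
    p1 = c1 + _sphere_points(r1, None, r_w, seed, 0.0)
    p2 = c2 + _sphere_points(r2, None, r_w, seed + 1, 0.0)
    merged = separation < r1 + r2
    passage_radius = 0.0
    if merged:
        d = separation
        x0 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
        ring = r1 * r1 - x0 * x0
        if ring <= 0:
            raise FixtureError("spheres overlap without an open intersection circle")
        passage_radius = math.sqrt(ring) - atom_radius
        keep1 = np.linalg.norm(p1 - c2, axis=1) >= r2
        keep2 = np.linalg.norm(p2 - c1, axis=1) >= r1
        p1, p2 = p1[keep1], p2[keep2]
    pts = np.vstack([p1, p2])
    n = len(pts)
    st = _build(pts, [residue_name] * n, ["A"] * n, atom_radius, "dumbbell")
    v1 = 4.0 / 3.0 * math.pi * (r1 - atom_radius) ** 3 / 1000.0
    v2 = 4.0 / 3.0 * math.pi * (r2 - atom_radius) ** 3 / 1000.0
    expected = {
        "kind": "dumbbell",
        "n_atoms": n,
        "merged": merged,
        "passage_clear_radius": passage_radius,
        "n_chambers": 1 if merged and passage_radius > r_w else 2,
        "v_c_nm3": max(v1, v2),
        "v_c_formula": "(4/3)*pi*(max(r1,r2) - r_atom)^3",
        "v_c_tol_rel": 0.10,
    }
    return st, expected


def make_hydropathy_shell(
    radius: float = 8.0,
    n_atoms: int = 200,
    mode: str = "uniform",
    residue_a: str = "ILE",
    residue_b: str = "ARG",
    atom_radius: float = 1.7,
    r_w: float = DEFAULT_PROBE_RADIUS,
    seed: int = 0,
) -> tuple[Structure, dict]:
    """Sealed shell with controlled residue labeling for hydropathy oracles.

    ``mode='uniform'`` stamps every pseudo-residue with ``residue_a`` (shell
    H = n × q_a exactly, h ≈ 0 by symmetry); ``mode='bipartite'`` labels the
    +z hemisphere ``residue_a`` and the −z hemisphere ``residue_b``, giving a
    hydropathy vector along −z→+z computable by direct summation.
    """
    pts = _sphere_points(radius, n_atoms, r_w, seed, 0.0)
    _check_sealed(pts, r_w)
    if mode == "uniform":
        names = [residue_a] * len(pts)
    elif mode == "bipartite":
        names = [residue_a if p[2] >= 0 else residue_b for p in pts]
    else:
        raise FixtureError(f"unknown labeling mode: {mode}")
    st = _build(pts, names, ["A"] * len(pts), atom_radius, f"hydropathy_shell_{mode}")
    expected = {
        "kind": "hydropathy_shell",
        "mode": mode,
        "n_atoms": len(pts),
        "residue_a": residue_a,
        "residue_b": residue_b,
    }
    return st, expected


def make_tetramer_ring(
    n_chains: int = 4,
    radius: float = 15.0,
    atom_radius: float = 1.7,
    n_atoms: int | None = None,
    gap_deg: float = 0.0,
    residue_name: str = "GLY",
    r_w: float = DEFAULT_PROBE_RADIUS,
    seed: int = 0,
) -> tuple[Structure, dict]:
    """Ring of chains that only jointly enclose a central void.

    The sealed shell is partitioned into ``n_chains`` azimuthal sectors, one
    chain each; any single chain is an open patch with no cavity of its own.
    ``gap_deg > 0`` removes atoms near sector boundaries, opening slits
    between the chains (wide gaps let the probe in and destroy the assembly
    cavity too).
    """
    if n_chains < 3:
        raise FixtureError("ring needs at least 3 chains")
    pts = _sphere_points(radius, n_atoms, r_w, seed, 0.0)
    if gap_deg == 0.0:
        _check_sealed(pts, r_w)
    phi = np.degrees(np.arctan2(pts[:, 1], pts[:, 0])) % 360.0
    sector = 360.0 / n_chains
    which = np.floor(phi / sector).astype(int)
    if gap_deg > 0.0:
        off = phi - which * sector
        keep = (off >= gap_deg / 2.0) & (off <= sector - gap_deg / 2.0)
        pts, which = pts[keep], which[keep]
    chain_ids = [chr(ord("A") + int(w)) for w in which]
    st = _build(pts, [residue_name] * len(pts), chain_ids, atom_radius, f"ring_{n_chains}")
    inner = radius - atom_radius
    expected = {
        "kind": "tetramer_ring",
        "n_chains": n_chains,
        "gap_deg": gap_deg,
        "n_atoms": len(pts),
        "assembly_v_c_nm3": 4.0 / 3.0 * math.pi * inner**3 / 1000.0 if gap_deg == 0 else None,
        "leaky": gap_deg > 0 and _gap_width(radius, gap_deg, atom_radius) > 2.0 * r_w,
    }
    return st, expected


def _gap_width(radius: float, gap_deg: float, atom_radius: float) -> float:
    """Approximate clear slit width (Å) opened by a boundary gap at the equator."""
    return radius * math.radians(gap_deg) - 2.0 * atom_radius


MAKERS = {
    "hollow_sphere": make_hollow_sphere,
    "open_cup": make_open_cup,
    "bored_sphere": make_bored_sphere,
    "dumbbell": make_dumbbell,
    "hydropathy_shell": make_hydropathy_shell,
    "tetramer_ring": make_tetramer_ring,
}
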