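"""Cavity-shell residue assignment and chemical/geometric descriptors.

The *shell* is the set of residues lining the cavity: for every
cavity-surface voxel, the residue owning the nearest atom (by center distance
minus van der Waals radius) joins the shell.  Descriptors over the shell:

* hydropathy ``H = Σ q_i`` — sum of Kyte–Doolittle indices, one term per
  shell residue (positive = hydrophobic wall);
* hydropathy vector ``h = Σ q_i δ_i`` with δ_i the residue position relative
  to the shell center of mass — its magnitude measures the hydropathy
  gradient across the cavity;
* radius of gyration ``R_g = sqrt(mean |r_k|²)`` over residue positions
  relative to the shell center of mass, in Å;
* inertia radii R_1 ≤ R_2 ≤ R_3 from the eigenvalues D_α of the
  mass-weighted inertia tensor of all shell atoms, R_α = sqrt(D_α / N_C)
  (N_C = number of shell residues, as published), and the shape parameter
  ``w = ΔR / R̄`` with R̄ = (R_1 + R_3)/2, ΔR = R_2 − R̄: w ≈ 0 for spheres,
  w > 0 for prolate (cigar) shells, w < 0 for oblate (planar) shells.

Residue positions default to mass-weighted atom centroids; Cα positions are
available by option.  Residues without a hydropathy index (non-standard
names) are excluded from H and h with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import Residue, Structure
from .surface import SurfaceMetrics

logger = logging.getLogger(__name__)


@dataclass
class ShellResidueSet:
    residues: list[Residue]
    com: np.ndarray | None  # (3,) Å, mass-weighted over all shell atoms

    @property
    def n_cp(self) -> int:
        return len(self.residues)


@dataclass
class DescriptorSet:
    n_cp: int
    h: float | None
    h_vec: np.ndarray | None  # (3,) hydropathy·Å
    h_norm: float | None
    h_per_residue: float | None
    r_g: float | None  # Å
    radii: tuple[float, float, float] | None  # R_1 ≤ R_2 ≤ R_3, Å-like units
    w: float | None
    r_bar: float | None
    delta_r: float | None
    n_excluded_kd: int = 0

    def to_dict(self) -> dict:
        return {
            "n_cp": self.n_cp,
            "h": self.h,
            "h_norm": self.h_norm,
            "h_per_residue": self.h_per_residue,
            "r_g": self.r_g,
            "r1": self.radii[0] if self.radii else None,
            "r2": self.radii[1] if self.radii else None,
            "r3": self.radii[2] if self.radii else None,
            "w": self.w,
            "n_excluded_kd": self.n_excluded_kd,
        }


def assign_shell(metrics: SurfaceMetrics, structure: Structure) -> ShellResidueSet:
    """Residues nearest to the cavity-surface voxels (union over the surface).

    Nearest means the smallest ``distance-to-atom-center − vdw_radius`` among
    the candidate atoms of each surface voxel.
    """
    if metrics.grid is None or len(metrics.surface_points) == 0:
        return ShellResidueSet(residues=[], com=None)
    world = metrics.grid.world_coords(metrics.surface_points)
    coords = structure.coords()
    radii = structure.radii()
    res_index = structure.atom_residue_index()
    tree = cKDTree(coords)
    k = min(24, len(coords))
    d, idx = tree.query(world, k=k)
    d = d.reshape(len(world), k)
    idx = idx.reshape(len(world), k)
    gap = d - radii[idx]
    best = idx[np.arange(len(world)), gap.argmin(axis=1)]
    shell_idx = np.unique(res_index[best])
    residues = [structure.residues[i] for i in shell_idx]
    atoms = [a for r in residues for a in r.atoms]
    m = np.array([a.mass for a in atoms])
    x = np.array([a.coords for a in atoms])
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    return ShellResidueSet(residues=residues, com=com)


def _residue_positions(shell: ShellResidueSet, use_c_alpha: bool = False) -> np.ndarray:
    pos = []
    for r in shell.residues:
        if use_c_alpha:
            ca = r.c_alpha()
            pos.append(ca if ca is not None else r.center_of_mass())
        else:
            pos.append(r.center_of_mass())
    return np.array(pos).reshape(-1, 3)


def hydropathy_H(shell: ShellResidueSet) -> tuple[float, int]:
    """Sum of Kyte–Doolittle indices over shell residues.

    Returns ``(H, n_excluded)`` where ``n_excluded`` counts residues without
    a defined index (excluded from the sum, logged).
    """
    total = 0.0
    excluded = 0
    for r in shell.residues:
        q = r.q
        if q is None:
            excluded += 1
        else:
            total += q
    if excluded:
        logger.warning("hydropathy sum: excluded %d residue(s) without KD index", excluded)
    return total, excluded


def hydropathy_vector(
    shell: ShellResidueSet, use_c_alpha: bool = False
) -> tuple[np.ndarray, float] | tuple[None, None]:
    """Hydropathy-weighted first moment of residue positions about the shell COM."""
    if shell.n_cp == 0 or shell.com is None:
        return None, None
    pos = _residue_positions(shell, use_c_alpha)
    q = np.array([r.q if r.q is not None else 0.0 for r in shell.residues])
    delta = pos - shell.com
    h_vec = (q[:, None] * delta).sum(axis=0)
    return h_vec, float(np.linalg.norm(h_vec))


def radius_of_gyration(shell: ShellResidueSet, use_c_alpha: bool = False) -> float | None:
    """RMS distance of shell-residue positions from the shell center of mass (Å)."""
    if shell.n_cp == 0 or shell.com is None:
        return None
    pos = _residue_positions(shell, use_c_alpha)
    r2 = ((pos - shell.com) ** 2).sum(axis=1)
    return float(np.sqrt(r2.mean()))


def shape_parameter(shell: ShellResidueSet):
    """Inertia radii (R_1 ≤ R_2 ≤ R_3) and shape parameter w of the shell.

    The inertia tensor ``I = Σ m (|r|² E − r rᵀ)`` is taken over all atoms of
    the shell residues about the shell center of mass; its eigenvalues D_α in
    ascending order give R_α = sqrt(D_α / N_C).  The residue-count
    normalization follows the published convention; only ratios of the R_α
    enter w, so the normalization cancels there.
    """
    if shell.n_cp < 3 or shell.com is None:
        return None, None, None, None
    atoms = [a for r in shell.residues for a in r.atoms]
    m = np.array([a.mass for a in atoms])
    x = np.array([a.coords for a in atoms]) - shell.com
    r2 = (x**2).sum(axis=1)
    inertia = (
        m[:, None, None]
        * (r2[:, None, None] * np.eye(3)[None] - x[:, :, None] * x[:, None, :])
    ).sum(axis=0)
    eigvals = np.linalg.eigvalsh(inertia)
    if eigvals[0] <= 0 or eigvals[2] <= 0:
        raise ValueError("degenerate (collinear) shell geometry")
    r_alpha = tuple(float(np.sqrt(ev / shell.n_cp)) for ev in eigvals)
    r_bar = 0.5 * (r_alpha[0] + r_alpha[2])
    delta_r = r_alpha[1] - r_bar
    w = delta_r / r_bar
    return r_alpha, w, r_bar, delta_r


def compute_descriptors(
    metrics: SurfaceMetrics, structure: Structure, use_c_alpha: bool = False
) -> DescriptorSet:
    """All shell descriptors for a surface-metrics result."""
    shell = assign_shell(metrics, structure)
    if shell.n_cp == 0:
        return DescriptorSet(
            n_cp=0, h=None, h_vec=None, h_norm=None, h_per_residue=None,
            r_g=None, radii=None, w=None, r_bar=None, delta_r=None,
        )
    h, excluded = hydropathy_H(shell)
    h_vec, h_norm = hydropathy_vector(shell, use_c_alpha)
    r_g = radius_of_gyration(shell, use_c_alpha)
    n_defined = shell.n_cp - excluded
    try:
        radii, w, r_bar, delta_r = shape_parameter(shell)
    except ValueError:
        radii = w = r_bar = delta_r = None
    return DescriptorSet(
        n_cp=shell.n_cp,
        h=h,
        h_vec=h_vec,
        h_norm=h_norm,
        h_per_residue=(h / n_defined) if n_defined else None,
        r_g=r_g,
        radii=radii,
        w=w,
        r_bar=r_bar,
        delta_r=delta_r,
        n_excluded_kd=excluded,
    )
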