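"""Cavity surface extraction, closure fraction s, and pocket classification.

The cavity surface is the rain-reachable boundary of the cavity's
probe-center point set: the rain is re-run against a pseudo-structure of
water spheres (radius r_w) placed on the CAVITY_CENTER grid points of the
selected chamber, which identifies the outer boundary of the point cloud —
boundary faces of sealed holes *inside* it are not cavity surface.  The
surface area S_C is the count of exposed voxel faces times a².

Each exposed face is split by what it borders: a face against protein
material (or the cavity's covering halo, which sits inside the wall) is
*contact* surface, summing to S_CP; a face against the rain-visited or
rain-covered exterior is part of the open lid closing the cavity.  The
closure fraction s = S_CP / S_C is 1 for a fully enclosed cavity and drops
as more of the boundary opens to the solvent; s below the survey-derived
threshold 0.21 (mean 0.36 minus three standard deviations of 0.05)
classifies the region as a pocket rather than a cavity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cavity import CavityResult
from .lattice import (
    CAVITY_COVERED,
    MATERIAL,
    RAIN_COVERED,
    RAIN_VISITED,
    LatticeGrid,
    ProbeParams,
)
from .structure import Structure

POCKET_THRESHOLD = 0.21  # s̄ − 3σ with s̄ = 0.36, σ = 0.05


@dataclass
class SurfaceMetrics:
    surface_points: np.ndarray  # (N, 3) grid indices of surface voxels
    face_counts: np.ndarray  # (N,) exposed faces per surface voxel
    contact_face_counts: np.ndarray  # (N,) faces bordering protein material
    contact: np.ndarray  # (N,) bool, voxel has ≥1 contact face
    s_c: float  # nm²
    s_cp: float  # nm²
    s: float | None  # closure fraction, None when S_C = 0
    label: str | None  # "cavity" | "pocket" | None
    threshold: float = POCKET_THRESHOLD
    grid: LatticeGrid | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "s_c_nm2": self.s_c,
            "s_cp_nm2": self.s_cp,
            "s": self.s,
            "label": self.label,
            "threshold": self.threshold,
            "n_surface_points": int(len(self.surface_points)),
        }


def _rain_visited(free: np.ndarray) -> np.ndarray:
    visited = np.zeros(free.shape, dtype=bool)
    for axis in range(3):
        visited |= np.logical_and.accumulate(free, axis=axis)
        rev = [slice(None)] * 3
        rev[axis] = slice(None, None, -1)
        rev = tuple(rev)
        visited |= np.logical_and.accumulate(free[rev], axis=axis)[rev]
    return visited


def _empty_metrics(grid: LatticeGrid | None) -> SurfaceMetrics:
    return SurfaceMetrics(
        surface_points=np.empty((0, 3), dtype=int),
        face_counts=np.empty(0, dtype=int),
        contact_face_counts=np.empty(0, dtype=int),
        contact=np.empty(0, dtype=bool),
        s_c=0.0,
        s_cp=0.0,
        s=None,
        label=None,
        grid=grid,
    )


def extract_surface(
    cavity: CavityResult | None,
    grid: LatticeGrid | None = None,
    center_mask: np.ndarray | None = None,
    params: ProbeParams | None = None,
) -> SurfaceMetrics:
    """Extract the cavity surface of the reference-rotation chamber.

    Either pass a :class:`CavityResult`, or (``grid``, ``center_mask``,
    ``params``) explicitly.  Surface voxels are cavity-center points with at
    least one exposed face that the pseudo-structure rain can reach from
    outside.  Fills S_C and the per-voxel face classification; the S_CP sum,
    s, and the label are applied by :func:`contact_split`.
    """
    if cavity is not None:
        grid = cavity.grid
        center_mask = cavity.center_mask
        params = cavity.params
    assert grid is not None and center_mask is not None and params is not None
    if not center_mask.any():
        return _empty_metrics(grid)

    # Rain on the pseudo-structure: a probe overlaps a cavity-placed water
    # sphere when the center distance is < 2 r_w.
    dist = ndimage.distance_transform_edt(~center_mask, sampling=grid.a)
    pseudo_blocked = dist < 2.0 * params.r_w
    visited = _rain_visited(~pseudo_blocked)
    if visited.any():
        dist_v = ndimage.distance_transform_edt(~visited, sampling=grid.a)
        # the rain front stops just short of 2 r_w from the outer boundary
        # centers; one lattice spacing of slack for quantization
        reachable = dist_v <= 2.0 * params.r_w + grid.a
    else:
        reachable = np.ones(grid.dims, dtype=bool)

    # classify exposed faces by the neighbor voxel's state
    state = grid.state
    wall_nb = (state == MATERIAL) | (state == CAVITY_COVERED)
    open_nb = (state == RAIN_VISITED) | (state == RAIN_COVERED)
    face_count = np.zeros(grid.dims, dtype=np.int8)
    contact_count = np.zeros(grid.dims, dtype=np.int8)
    non_center = ~center_mask
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        face_count[lo] += (center_mask[lo] & non_center[hi]).astype(np.int8)
        face_count[hi] += (center_mask[hi] & non_center[lo]).astype(np.int8)
        contact_count[lo] += (center_mask[lo] & wall_nb[hi]).astype(np.int8)
        contact_count[hi] += (center_mask[hi] & wall_nb[lo]).astype(np.int8)
    del open_nb  # open faces = face_count − contact_count by construction

    surface_mask = center_mask & (face_count > 0) & reachable
    pts = np.argwhere(surface_mask)
    counts = face_count[surface_mask].astype(int)
    contact_counts = contact_count[surface_mask].astype(int)
    s_c = float(counts.sum()) * params.a**2 / 100.0  # nm²
    return SurfaceMetrics(
        surface_points=pts,
        face_counts=counts,
        contact_face_counts=contact_counts,
        contact=contact_counts > 0,
        s_c=s_c,
        s_cp=0.0,
        s=None,
        label=None,
        grid=grid,
    )


def contact_split(
    metrics: SurfaceMetrics,
    structure: Structure | None = None,
    params: ProbeParams | None = None,
    threshold: float = POCKET_THRESHOLD,
) -> SurfaceMetrics:
    """Compute S_CP, the closure fraction s, and the pocket/cavity label.

    Contact surface is the set of exposed faces bordering protein material or
    the cavity halo (which lies within one probe radius of the wall atoms);
    the remaining faces border the rain-reached exterior and form the open
    lid.  ``structure``/``params`` are accepted for interface symmetry with
    the extraction step; the face classification is grid-native.
    """
    if metrics.s_c == 0.0 or len(metrics.surface_points) == 0:
        metrics.s = None
        metrics.label = None
        return metrics
    a = metrics.grid.a if metrics.grid is not None else (params.a if params else 0.6)
    metrics.s_cp = float(metrics.contact_face_counts.sum()) * a**2 / 100.0
    metrics.s = metrics.s_cp / metrics.s_c
    metrics.threshold = threshold
    metrics.label = classify_pocket(metrics.s, threshold)
    return metrics


def classify_pocket(s: float, threshold: float = POCKET_THRESHOLD) -> str:
    """Label a closure fraction: 'pocket' iff s < threshold (strict)."""
    if not 0.0 <= s <= 1.0 + 1e-12:
        raise ValueError(f"closure fraction out of range: {s}")
    return "pocket" if s < threshold else "cavity"


def compute_surface_metrics(
    cavity: CavityResult,
    threshold: float = POCKET_THRESHOLD,
) -> SurfaceMetrics:
    """Convenience: extract the surface and split it against the protein."""
    metrics = extract_surface(cavity)
    return contact_split(metrics, cavity.rotated_structure, cavity.params, threshold)
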