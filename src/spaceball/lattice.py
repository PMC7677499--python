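"""Voxel lattice, random rotations, and the six-wall probe "rain".

The structure sits in an axis-aligned cuboid box carved into a cubic grid of
spacing ``a``.  Spherical water probes of radius ``r_w`` march inward from
each of the six box walls along every perpendicular grid line, one lattice
step at a time, marking the points they visit; a ray halts permanently at the
first position where the probe sphere overlaps any atom sphere (strict
overlap: center distance < r_w + r_atom).  Points within r_w of a visited
point are additionally marked as covered — together these define the outside
of the structure.  Because ``a < r_w`` a probe cannot tunnel past a blocking
atom between consecutive steps.

Orientation bias of the axis-aligned rays is averaged out by repeating the
whole procedure for several uniformly random rotations of the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .structure import Structure

# grid state labels
UNSEEN = 0
RAIN_VISITED = 1
RAIN_COVERED = 2
MATERIAL = 3
CAVITY_CENTER = 4
CAVITY_COVERED = 5

STATE_NAMES = {
    UNSEEN: "UNSEEN",
    RAIN_VISITED: "RAIN_VISITED",
    RAIN_COVERED: "RAIN_COVERED",
    MATERIAL: "MATERIAL",
    CAVITY_CENTER: "CAVITY_CENTER",
    CAVITY_COVERED: "CAVITY_COVERED",
}


@dataclass
class ProbeParams:
    """Parameters of the probe lattice protocol.

    Defaults are the survey conditions: water-probe radius r_w = 1.42 Å,
    lattice constant a = 0.6 Å, five random rotations.
    """

    r_w: float = 1.42
    a: float = 0.6
    n_rotations: int = 5
    seed: int = 0
    padding: float | None = None  # default: max_vdw + 2 r_w + 3 a
    vt_includes_cavity: bool = False

    def __post_init__(self) -> None:
        if self.r_w <= 0:
            raise ValueError("probe radius must be positive")
        if not 0 < self.a < self.r_w:
            raise ValueError("lattice constant must satisfy 0 < a < r_w")
        if self.n_rotations < 1:
            raise ValueError("need at least one rotation")

    def fingerprint(self) -> dict:
        return {
            "a": self.a,
            "r_w": self.r_w,
            "n_rotations": self.n_rotations,
            "seed": self.seed,
            "vt_includes_cavity": self.vt_includes_cavity,
        }


@dataclass
class LatticeGrid:
    origin: np.ndarray  # (3,) Å, coordinates of grid point (0,0,0)
    a: float
    dims: tuple[int, int, int]
    state: np.ndarray = field(repr=False)  # uint8, shape dims
    blocked: np.ndarray | None = field(default=None, repr=False)  # probe-overlap mask

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def world_coords(self, idx: np.ndarray) -> np.ndarray:
        """Convert (N, 3) grid indices to Å coordinates."""
        return self.origin[None, :] + np.asarray(idx, dtype=float) * self.a


def build_box(structure: Structure, params: ProbeParams) -> LatticeGrid:
    """Build the padded axis-aligned grid box around the structure.

    Padding on every side is at least ``max_vdw + 2 r_w + 3 a`` beyond the
    atom spheres, so rain rays always start well outside the structure and the
    covering dilation never touches the box walls.
    """
    if len(structure) == 0:
        raise ValueError("cannot build a box around an empty structure")
    coords = structure.coords()
    radii = structure.radii()
    pad = params.padding
    if pad is None:
        pad = float(radii.max()) + 2.0 * params.r_w + 3.0 * params.a
    lo = (coords - radii[:, None]).min(axis=0) - pad
    hi = (coords + radii[:, None]).max(axis=0) + pad
    dims = tuple(int(np.ceil((hi[k] - lo[k]) / params.a)) + 1 for k in range(3))
    state = np.zeros(dims, dtype=np.uint8)
    return LatticeGrid(origin=lo, a=params.a, dims=dims, state=state)


def random_rotation(seed: int, index: int) -> np.ndarray:
    """Uniformly random proper rotation matrix, reproducible per (seed, index).

    Uses the normalized-Gaussian quaternion construction, which is uniform on
    SO(3).
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, int(index)])
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotate_structure(structure: Structure, rotation: np.ndarray) -> Structure:
    """Rotate the structure about its centroid."""
    center = structure.centroid()
    coords = (structure.coords() - center) @ rotation.T + center
    return structure.with_coords(coords)


def compute_blocked(grid: LatticeGrid, structure: Structure, params: ProbeParams) -> np.ndarray:
    """Boolean mask of grid points where the probe overlaps some atom sphere.

    A point is blocked when its distance to an atom center is strictly less
    than r_w + r_atom (touching spheres do not block).
    """
    blocked = np.zeros(grid.dims, dtype=bool)
    coords = structure.coords()
    radii = structure.radii()
    a = grid.a
    origin = grid.origin
    dims = np.array(grid.dims)
    for c, r in zip(coords, radii):
        reach = r + params.r_w
        lo = np.maximum(np.ceil((c - reach - origin) / a).astype(int), 0)
        hi = np.minimum(np.floor((c - origin + reach) / a).astype(int), dims - 1)
        if np.any(hi < lo):
            continue
        ax = [origin[k] + a * np.arange(lo[k], hi[k] + 1) - c[k] for k in range(3)]
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        sub = blocked[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        sub |= d2 < reach * reach
    return blocked


def _within(mask: np.ndarray, radius: float, a: float) -> np.ndarray:
    """Points whose Euclidean distance to the nearest True point is ≤ radius."""
    if not mask.any():
        return np.zeros_like(mask)
    dist = ndimage.distance_transform_edt(~mask, sampling=a)
    return dist <= radius


def rain(grid: LatticeGrid, structure: Structure, params: ProbeParams) -> LatticeGrid:
    """Run the six-wall rain and mark RAIN_VISITED / RAIN_COVERED points.

    The blocked mask is cached on the grid for the later classification and
    entrance steps.
    """
    blocked = compute_blocked(grid, structure, params)
    free = ~blocked
    visited = np.zeros(grid.dims, dtype=bool)
    for axis in range(3):
        # from the low wall: a point is visited if every point from the wall
        # up to and including itself is probe-free
        visited |= np.logical_and.accumulate(free, axis=axis)
        rev = [slice(None)] * 3
        rev[axis] = slice(None, None, -1)
        rev = tuple(rev)
        visited |= np.logical_and.accumulate(free[rev], axis=axis)[rev]
    covered = _within(visited, params.r_w, grid.a) & ~visited

    grid.state[:] = UNSEEN
    grid.state[visited] = RAIN_VISITED
    grid.state[covered] = RAIN_COVERED
    grid.blocked = blocked
    return grid
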