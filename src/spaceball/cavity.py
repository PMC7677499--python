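"""Cavity classification, chamber labeling, volumes, entrances, and the
rotation-averaged driver.

After the rain, every still-unseen grid point is tested with the probe: if
the probe overlaps an atom sphere the point belongs to the structure
(MATERIAL), otherwise it is a cavity center (CAVITY_CENTER).  Material points
within one probe radius of a cavity center form the cavity's covering halo
(CAVITY_COVERED) and are counted as cavity volume.  Connected components of
cavity centers under face adjacency are the chambers; the largest chamber
(centers plus halo) defines the cavity volume V_C, and material points define
the total structure volume V_T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .lattice import (
    CAVITY_CENTER,
    CAVITY_COVERED,
    MATERIAL,
    RAIN_COVERED,
    RAIN_VISITED,
    UNSEEN,
    LatticeGrid,
    ProbeParams,
    _within,
    build_box,
    compute_blocked,
    rain,
    random_rotation,
    rotate_structure,
)
from .structure import Structure

_FACE_CONN = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def classify_points(grid: LatticeGrid, structure: Structure, params: ProbeParams) -> LatticeGrid:
    """Split UNSEEN points into MATERIAL / CAVITY_CENTER and mark the halo."""
    if grid.blocked is None:
        grid.blocked = compute_blocked(grid, structure, params)
    unseen = grid.state == UNSEEN
    material = unseen & grid.blocked
    centers = unseen & ~grid.blocked
    halo = material & _within(centers, params.r_w, grid.a)
    grid.state[material] = MATERIAL
    grid.state[centers] = CAVITY_CENTER
    grid.state[halo] = CAVITY_COVERED
    return grid


def label_chambers(grid: LatticeGrid, params: ProbeParams):
    """Label connected chambers and attach the covering halo to each.

    Centers are grouped under 6-connectivity (face adjacency), which keeps
    voids that merely touch at corners separate.  Each halo point is claimed
    by the chambers whose centers lie within r_w; when several claim it, the
    chamber with more center points wins (ties to the lower label).

    Returns ``(labels, sizes)`` where ``labels`` is an int array (0 = not
    cavity) and ``sizes`` maps label → total point count (centers + halo).
    """
    centers = grid.state == CAVITY_CENTER
    halo = grid.state == CAVITY_COVERED
    labels, n = ndimage.label(centers, structure=_FACE_CONN)
    sizes: dict[int, int] = {}
    if n == 0:
        return labels, sizes
    center_counts = ndimage.sum_labels(centers, labels, index=np.arange(1, n + 1))
    order = sorted(range(1, n + 1), key=lambda l: (-center_counts[l - 1], l))
    halo_labels = np.zeros_like(labels)
    unclaimed = halo.copy()
    objects = ndimage.find_objects(labels)
    margin = int(np.ceil(params.r_w / grid.a)) + 1
    for lab in order:
        if not unclaimed.any():
            break
        sl = objects[lab - 1]
        window = tuple(
            slice(max(s.start - margin, 0), min(s.stop + margin, grid.dims[k]))
            for k, s in enumerate(sl)
        )
        near = _within(labels[window] == lab, params.r_w, grid.a)
        claim = unclaimed[window] & near
        halo_labels[window][claim] = lab
        unclaimed[window][claim] = False
    full = np.where(labels > 0, labels, halo_labels)
    for lab in range(1, n + 1):
        sizes[lab] = int(center_counts[lab - 1]) + int(np.count_nonzero(halo_labels == lab))
    return full, sizes


def measure_volumes(grid: LatticeGrid, labels: np.ndarray, sizes: dict[int, int], params: ProbeParams):
    """Compute V_T and V_C in nm³ from point counts (1 nm³ = 1000 Å³)."""
    a3 = params.a**3 / 1000.0
    n_material = int(np.count_nonzero(grid.state == MATERIAL))
    if sizes:
        largest = min(sizes, key=lambda l: (-sizes[l], l))
        v_c = sizes[largest] * a3
    else:
        largest = 0
        v_c = 0.0
    n_cavity = int(sum(sizes.values()))
    v_t = (n_material + n_cavity) * a3 if params.vt_includes_cavity else n_material * a3
    return v_t, v_c, largest


def find_entrances(grid: LatticeGrid, chamber_mask: np.ndarray) -> np.ndarray:
    """Cavity points where the chamber opens onto the rain-reached exterior.

    An entrance point is a chamber point (center or halo) with a face
    neighbor that the rain reached — i.e. a point sitting on a straight-line
    corridor connecting the cavity to the outside with no protein atoms in
    between.  A fully sealed cavity has an empty entrance set; a chamber
    reached through a bore or an open face exposes its mouth here.  Returns
    (N, 3) grid indices.
    """
    exterior = (grid.state == RAIN_VISITED) | (grid.state == RAIN_COVERED)
    near_exterior = np.zeros(grid.dims, dtype=bool)
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        near_exterior[lo] |= exterior[hi]
        near_exterior[hi] |= exterior[lo]
    return np.argwhere(chamber_mask & near_exterior)


@dataclass
class RotationRecord:
    index: int
    v_t: float  # nm³
    v_c: float  # nm³
    chamber_sizes_nm3: list[float]
    n_chambers: int
    n_entrance_points: int


@dataclass
class CavityResult:
    """Result of a rotation-averaged cavity run."""

    structure_id: str
    params: ProbeParams
    rotations: list[RotationRecord]
    v_t_mean: float
    v_t_std: float
    v_c_mean: float
    v_c_std: float
    reference_rotation: int
    # full state for the reference rotation (used downstream for surface and
    # descriptor analysis):
    grid: LatticeGrid = field(repr=False)
    labels: np.ndarray = field(repr=False)
    largest_label: int
    rotated_structure: Structure = field(repr=False)
    entrances: np.ndarray = field(repr=False)  # (N, 3) grid indices

    @property
    def v_c(self) -> float:
        return self.v_c_mean

    @property
    def v_t(self) -> float:
        return self.v_t_mean

    @property
    def chamber_mask(self) -> np.ndarray:
        return self.labels == self.largest_label if self.largest_label else np.zeros(self.grid.dims, bool)

    @property
    def center_mask(self) -> np.ndarray:
        return self.chamber_mask & (self.grid.state == CAVITY_CENTER)

    def to_dict(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "params": self.params.fingerprint(),
            "v_t_mean_nm3": self.v_t_mean,
            "v_t_std_nm3": self.v_t_std,
            "v_c_mean_nm3": self.v_c_mean,
            "v_c_std_nm3": self.v_c_std,
            "reference_rotation": self.reference_rotation,
            "rotations": [
                {
                    "index": r.index,
                    "v_t_nm3": r.v_t,
                    "v_c_nm3": r.v_c,
                    "n_chambers": r.n_chambers,
                    "chamber_sizes_nm3": r.chamber_sizes_nm3,
                    "n_entrance_points": r.n_entrance_points,
                }
                for r in self.rotations
            ],
        }


def _single_run(structure: Structure, params: ProbeParams):
    grid = build_box(structure, params)
    rain(grid, structure, params)
    classify_points(grid, structure, params)
    labels, sizes = label_chambers(grid, params)
    v_t, v_c, largest = measure_volumes(grid, labels, sizes, params)
    chamber_mask = labels == largest if largest else np.zeros(grid.dims, bool)
    entrances = find_entrances(grid, chamber_mask)
    a3 = params.a**3 / 1000.0
    record_sizes = sorted((s * a3 for s in sizes.values()), reverse=True)
    return grid, labels, largest, v_t, v_c, record_sizes, entrances


def run_spaceball(structure: Structure, params: ProbeParams) -> CavityResult:
    """Full pipeline: build → rain → classify → label → measure per rotation.

    V_T and V_C are summarized as mean ± sample standard deviation over the
    rotations.  The rotation with the median V_C (lower median for an even
    count) is kept in full as the reference for surface and descriptor work.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    records: list[RotationRecord] = []
    kept: dict[int, tuple] = {}
    for i in range(params.n_rotations):
        rot = random_rotation(params.seed, i)
        rotated = rotate_structure(structure, rot)
        grid, labels, largest, v_t, v_c, sizes, entrances = _single_run(rotated, params)
        records.append(
            RotationRecord(
                index=i,
                v_t=v_t,
                v_c=v_c,
                chamber_sizes_nm3=sizes,
                n_chambers=len(sizes),
                n_entrance_points=len(entrances),
            )
        )
        kept[i] = (grid, labels, largest, rotated, entrances)

    v_cs = [r.v_c for r in records]
    v_ts = [r.v_t for r in records]
    order = sorted(range(len(v_cs)), key=lambda i: (v_cs[i], i))
    ref = order[(len(order) - 1) // 2]
    grid, labels, largest, rotated, entrances = kept[ref]
    # release the non-reference grids
    kept = {}
    n = len(records)
    ddof = 1 if n > 1 else 0
    return CavityResult(
        structure_id=structure.id,
        params=params,
        rotations=records,
        v_t_mean=float(np.mean(v_ts)),
        v_t_std=float(np.std(v_ts, ddof=ddof)) if n > 1 else 0.0,
        v_c_mean=float(np.mean(v_cs)),
        v_c_std=float(np.std(v_cs, ddof=ddof)) if n > 1 else 0.0,
        reference_rotation=ref,
        grid=grid,
        labels=labels,
        largest_label=largest,
        rotated_structure=rotated,
        entrances=entrances,
    )
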