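"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the production code paths: blocking is computed
from the full point-to-atom distance matrix, visited status by casting each
of the six axis rays per point and testing every probe position along the
ray, and coverage/halo by KD-tree nearest-distance queries (the production
code stamps per-atom spheres, marches accumulating rays, and uses Euclidean
distance transforms).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

UNSEEN, RAIN_VISITED, RAIN_COVERED, MATERIAL, CAVITY_CENTER, CAVITY_COVERED = range(6)


def _grid_points(origin, a, dims):
    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    return origin + a * idx


def brute_blocked(origin, a, dims, coords, radii, r_w):
    """Probe-overlap test from the full point×atom distance matrix."""
    pts = _grid_points(origin, a, dims)
    reach = np.asarray(radii) + r_w
    blocked = np.zeros(len(pts), dtype=bool)
    step = 20000  # keep the distance matrix small
    for s in range(0, len(pts), step):
        d = np.sqrt(((pts[s : s + step, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
        blocked[s : s + step] = (d < reach[None, :]).any(axis=1)
    return blocked.reshape(dims)


def brute_visited(blocked):
    """For each point and each of six directions, test the whole ray."""
    nx, ny, nz = blocked.shape
    visited = np.zeros(blocked.shape, dtype=bool)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if blocked[i, j, k]:
                    continue
                if not blocked[: i + 1, j, k].any() or not blocked[i:, j, k].any():
                    visited[i, j, k] = True
                    continue
                if not blocked[i, : j + 1, k].any() or not blocked[i, j:, k].any():
                    visited[i, j, k] = True
                    continue
                if not blocked[i, j, : k + 1].any() or not blocked[i, j, k:].any():
                    visited[i, j, k] = True
    return visited


def brute_within(mask, radius, a):
    """Points within Euclidean distance ``radius`` of any True point."""
    out = np.zeros(mask.shape, dtype=bool)
    src = np.argwhere(mask).astype(float) * a
    if len(src) == 0:
        return out
    tree = cKDTree(src)
    pts = _grid_points(np.zeros(3), a, mask.shape)
    d, _ = tree.query(pts)
    return (d <= radius).reshape(mask.shape)


def brute_state(origin, a, dims, coords, radii, r_w):
    """Full rain + classification state array, brute force end to end."""
    blocked = brute_blocked(origin, a, dims, coords, radii, r_w)
    visited = brute_visited(blocked)
    covered = brute_within(visited, r_w, a) & ~visited
    unseen = ~visited & ~covered
    material = unseen & blocked
    centers = unseen & ~blocked
    halo = material & brute_within(centers, r_w, a)
    state = np.full(dims, UNSEEN, dtype=np.uint8)
    state[visited] = RAIN_VISITED
    state[covered] = RAIN_COVERED
    state[material & ~halo] = MATERIAL
    state[centers] = CAVITY_CENTER
    state[halo] = CAVITY_COVERED
    return state
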