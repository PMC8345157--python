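"""Independent brute-force oracles used by the test suite.

Each oracle enumerates the defining objects directly (voxel pairs, runs,
connected components, ray crossings) in plain Python so that it shares no
code with the implementation under test.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np


def glcm_oracle(
    levels: np.ndarray, mask: np.ndarray, offset: Sequence[int], G: int
) -> np.ndarray:
    """Symmetrised co-occurrence counts by explicit ordered-pair enumeration."""
    counts = np.zeros((G, G))
    nz, ny, nx = levels.shape
    dz, dy, dx = offset
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                z2, y2, x2 = z + dz, y + dy, x + dx
                if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx and mask[z2, y2, x2]:
                    i, j = levels[z, y, x] - 1, levels[z2, y2, x2] - 1
                    counts[i, j] += 1
                    counts[j, i] += 1  # symmetrisation = ordered pair + transpose
    return counts


def runs_oracle(
    levels: np.ndarray, mask: np.ndarray, offset: Sequence[int], G: int
) -> np.ndarray:
    """Run-length counts by walking every line along the direction."""
    d = tuple(int(v) for v in offset)
    axis = next(a for a in range(3) if d[a] != 0)
    if d[axis] < 0:
        d = tuple(-v for v in d)
    shape = levels.shape
    runs: List[Tuple[int, int]] = []  # (level, length)
    # line starts: voxels whose predecessor along d is outside the array
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                pz, py, px = z - d[0], y - d[1], x - d[2]
                if 0 <= pz < shape[0] and 0 <= py < shape[1] and 0 <= px < shape[2]:
                    continue
                # walk the line, collecting maximal mask-contiguous equal runs
                cz, cy, cx = z, y, x
                cur_level, cur_len = None, 0
                while 0 <= cz < shape[0] and 0 <= cy < shape[1] and 0 <= cx < shape[2]:
                    if mask[cz, cy, cx]:
                        lev = int(levels[cz, cy, cx])
                        if lev == cur_level:
                            cur_len += 1
                        else:
                            if cur_level is not None:
                                runs.append((cur_level, cur_len))
                            cur_level, cur_len = lev, 1
                    else:
                        if cur_level is not None:
                            runs.append((cur_level, cur_len))
                        cur_level, cur_len = None, 0
                    cz, cy, cx = cz + d[0], cy + d[1], cx + d[2]
                if cur_level is not None:
                    runs.append((cur_level, cur_len))
    if not runs:
        return np.zeros((G, 1))
    max_len = max(length for _, length in runs)
    counts = np.zeros((G, max_len))
    for lev, length in runs:
        counts[lev - 1, length - 1] += 1
    return counts


def zones_oracle(levels: np.ndarray, mask: np.ndarray) -> Dict[int, List[int]]:
    """Connected equal-level component sizes by breadth-first search.

    Connectivity includes diagonals (26 in 3D, 8 in 2D).
    """
    arr = levels
    nd = arr.ndim
    shape = arr.shape
    visited = np.zeros(shape, dtype=bool)
    offsets = [
        off
        for off in np.ndindex(*(3,) * nd)
        if any(o != 1 for o in off)
    ]
    offsets = [tuple(o - 1 for o in off) for off in offsets]
    out: Dict[int, List[int]] = {}
    for idx in np.ndindex(*shape):
        if not mask[idx] or visited[idx]:
            continue
        lev = int(arr[idx])
        stack = [idx]
        visited[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in offsets:
                nxt = tuple(c + o for c, o in zip(cur, off))
                if any(n < 0 or n >= s for n, s in zip(nxt, shape)):
                    continue
                if mask[nxt] and not visited[nxt] and int(arr[nxt]) == lev:
                    visited[nxt] = True
                    stack.append(nxt)
        out.setdefault(lev, []).append(size)
    for sizes in out.values():
        sizes.sort()
    return out


def zone_matrix_oracle(per_level: Dict[int, List[int]], G: int) -> np.ndarray:
    max_size = max((max(s) for s in per_level.values()), default=1)
    counts = np.zeros((G, max_size))
    for lev, sizes in per_level.items():
        for s in sizes:
            counts[lev - 1, s - 1] += 1
    return counts


def point_in_polygon_oracle(px: float, py: float, vertices: np.ndarray) -> bool:
    """Even-odd rule by explicit ray casting (ray towards +x)."""
    inside = False
    n = len(vertices)
    for k in range(n):
        x1, y1 = vertices[k][:2]
        x2, y2 = vertices[(k + 1) % n][:2]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if x_cross > px:
                inside = not inside
    return inside
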