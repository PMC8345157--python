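"""Texture-matrix builders: co-occurrence, run-length and size-zone counts.

All builders operate on a :class:`~dosetex.preprocessing.DiscretisedRoi`
(grey levels 1..G inside the mask, 0 outside).  Conventions:

* co-occurrence: Chebyshev distance-1 offsets, ordered pairs symmetrised by
  adding the transpose;
* run-length: maximal runs of equal level along a direction, truncated at the
  mask boundary (and at gaps in the mask);
* size-zone: zones are connected components of equal level, 26-connectivity
  in 3D and 8-connectivity within 2D slices.

The 13 unique 3D directions are one representative per +/- pair of the 26
Chebyshev neighbours; the 4 in-plane directions are their (dz = 0) subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from ..preprocessing import DiscretisedRoi

DIRECTIONS_2D: Tuple[Tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (0, 1, 1),
    (0, 1, -1),
)

DIRECTIONS_3D: Tuple[Tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


@dataclass
class TextureMatrix:
    """A counted (not yet normalised) texture matrix plus provenance."""

    kind: str  # cooccurrence | runlength | sizezone
    counts: np.ndarray
    n_voxels: int  # voxels contributing (x number of merged directions)
    provenance: str = ""
    empty: bool = False
    flags: List[str] = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalised(self) -> np.ndarray:
        total = self.total
        if total == 0:
            raise ValueError(f"cannot normalise an empty {self.kind} matrix")
        return self.counts / total


def _offset_slices(shape: Sequence[int], offset: Sequence[int]):
    """Paired slicings such that src[sl_a][v] and src[sl_b][v] differ by offset."""
    sl_a, sl_b = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return tuple(sl_a), tuple(sl_b)


# --------------------------------------------------------------------------
# Co-occurrence
# --------------------------------------------------------------------------

def glcm_counts(
    levels: np.ndarray, mask: np.ndarray, offset: Sequence[int], G: int
) -> np.ndarray:
    """Symmetrised co-occurrence counts for one voxel offset."""
    if max(abs(int(d)) for d in offset) != 1:
        raise ValueError(f"offset {offset} is not a Chebyshev distance-1 displacement")
    sl_a, sl_b = _offset_slices(levels.shape, offset)
    valid = mask[sl_a] & mask[sl_b]
    i = levels[sl_a][valid] - 1
    j = levels[sl_b][valid] - 1
    counts = np.bincount(i * G + j, minlength=G * G).reshape(G, G).astype(np.float64)
    return counts + counts.T


def cooccurrence_matrix(
    roi: DiscretisedRoi, offset: Sequence[int], mode: str = "3D"
) -> TextureMatrix:
    """Co-occurrence matrix for one offset, volumetric or accumulated per slice.

    In ``2D_slice`` mode the offset must lie in-plane (dz = 0) and counts are
    accumulated over slices.
    """
    if mode not in ("3D", "2D_slice"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "2D_slice":
        if offset[0] != 0:
            raise ValueError("2D_slice mode requires an in-plane offset (dz = 0)")
        counts = np.zeros((roi.G, roi.G))
        for k in range(roi.levels.shape[0]):
            if roi.mask[k].any():
                counts += glcm_counts(
                    roi.levels[k][None], roi.mask[k][None], offset, roi.G
                )
    else:
        counts = glcm_counts(roi.levels, roi.mask, offset, roi.G)
    empty = counts.sum() == 0
    return TextureMatrix(
        kind="cooccurrence",
        counts=counts,
        n_voxels=roi.n_voxels,
        provenance=f"offset={tuple(offset)} mode={mode}",
        empty=bool(empty),
        flags=["no_valid_pairs"] if empty else [],
    )


# --------------------------------------------------------------------------
# Run length
# --------------------------------------------------------------------------

def _shift_towards(arr: np.ndarray, offset: Sequence[int], fill) -> np.ndarray:
    """Return ``out[v] = arr[v + offset]`` with ``fill`` outside the array."""
    out = np.full_like(arr, fill)
    sl_a, sl_b = _offset_slices(arr.shape, offset)
    out[sl_a] = arr[sl_b]
    return out


def run_length_counts(
    levels: np.ndarray, mask: np.ndarray, offset: Sequence[int], G: int
) -> np.ndarray:
    """Run-length counts ``R[level-1, length-1]`` along one direction.

    Runs are maximal sequences of equal grey level along ``offset``; they are
    truncated wherever the mask is interrupted.
    """
    d = tuple(int(v) for v in offset)
    if max(abs(v) for v in d) != 1:
        raise ValueError(f"offset {offset} is not a Chebyshev distance-1 displacement")
    axis = next(a for a in range(3) if d[a] != 0)
    if d[axis] < 0:  # runs are direction-sign invariant
        d = tuple(-v for v in d)

    same_fwd = mask & _shift_towards(mask, d, False)
    same_fwd &= levels == _shift_towards(levels, d, -1)

    # run length per voxel: 1 + length at the forward neighbour when the run
    # continues; filled by sweeping planes perpendicular to `axis` in reverse
    runlen = mask.astype(np.int64)
    n = levels.shape[axis]
    rest = tuple(v for a, v in enumerate(d) if a != axis)

    def plane(arr: np.ndarray, t: int) -> np.ndarray:
        idx = [slice(None)] * 3
        idx[axis] = t
        return arr[tuple(idx)]

    for t in range(n - 2, -1, -1):
        nxt = plane(runlen, t + 1)
        if any(rest):
            shifted = np.full_like(nxt, 0)
            sl_a, sl_b = _offset_slices(nxt.shape, rest)
            shifted[sl_a] = nxt[sl_b]
        else:
            shifted = nxt
        cur = plane(runlen, t)
        cont = plane(same_fwd, t)
        cur[cont] += shifted[cont]

    # a run starts where the backward neighbour does not continue the run
    starts = mask & ~_shift_towards(same_fwd, tuple(-v for v in d), False)
    lev = levels[starts] - 1
    lengths = runlen[starts]
    if lengths.size == 0:
        return np.zeros((G, 1))
    max_len = int(lengths.max())
    counts = np.zeros((G, max_len))
    np.add.at(counts, (lev, lengths - 1), 1.0)
    return counts


def run_length_matrix(
    roi: DiscretisedRoi, offset: Sequence[int], mode: str = "3D"
) -> TextureMatrix:
    """Run-length matrix for one direction (volumetric or per-slice summed)."""
    if mode not in ("3D", "2D_slice"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "2D_slice" and offset[0] != 0:
        raise ValueError("2D_slice mode requires an in-plane offset (dz = 0)")
    counts = run_length_counts(roi.levels, roi.mask, offset, roi.G)
    empty = counts.sum() == 0
    return TextureMatrix(
        kind="runlength",
        counts=counts,
        n_voxels=roi.n_voxels,
        provenance=f"offset={tuple(offset)} mode={mode}",
        empty=bool(empty),
        flags=["no_runs"] if empty else [],
    )


# --------------------------------------------------------------------------
# Size zone
# --------------------------------------------------------------------------

def zone_sizes(
    levels: np.ndarray, mask: np.ndarray, G: int, connectivity: Optional[np.ndarray] = None
) -> Dict[int, List[int]]:
    """Sizes of the connected equal-level components, per grey level."""
    if connectivity is None:
        connectivity = np.ones((3,) * levels.ndim, dtype=int)  # 26- / 8-connectivity
    present = np.unique(levels[mask]) if mask.any() else np.array([], dtype=int)
    out: Dict[int, List[int]] = {}
    for g in present:
        labelled, n = ndimage.label(levels == g, structure=connectivity)
        if n:
            sizes = np.bincount(labelled.ravel())[1:]
            out[int(g)] = [int(s) for s in sizes if s > 0]
    return out


def size_zone_matrix(roi: DiscretisedRoi, mode: str = "3D") -> TextureMatrix:
    """Size-zone matrix: 3D (26-connectivity) or slice-merged 2D (8-conn.)."""
    if mode not in ("3D", "2D_merge"):
        raise ValueError(f"unknown mode {mode!r}")
    per_level: Dict[int, List[int]] = {}
    if mode == "3D":
        per_level = zone_sizes(roi.levels, roi.mask, roi.G)
    else:
        for k in range(roi.levels.shape[0]):
            if not roi.mask[k].any():
                continue
            for g, sizes in zone_sizes(roi.levels[k], roi.mask[k], roi.G).items():
                per_level.setdefault(g, []).extend(sizes)
    max_size = max((max(s) for s in per_level.values()), default=1)
    counts = np.zeros((roi.G, max_size))
    for g, sizes in per_level.items():
        for s in sizes:
            counts[g - 1, s - 1] += 1.0
    empty = counts.sum() == 0
    return TextureMatrix(
        kind="sizezone",
        counts=counts,
        n_voxels=roi.n_voxels,
        provenance=f"mode={mode}",
        empty=bool(empty),
        flags=["no_zones"] if empty else [],
    )
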