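"""Grid alignment, contour rasterisation and grey-level discretisation.

Discretisation maps absolute dose (Gy) to ``G`` integer grey levels (default
100) spanning zero to the maximum dose, the convention used when treating a
dose distribution as a texture image.  The maximum may be taken per ROI
(default: keeps level occupancy comparable across ROIs) or over the whole
grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage

from .core import Grid, DoseGrid, RoiMask
from .rt_io import ContourSet


class DiscretisationError(ValueError):
    """Raised when a grey-level range cannot be defined."""


@dataclass
class DiscretisedRoi:
    """Integer grey levels in [1, G] over the masked voxels of one ROI.

    ``levels`` is a full 3D int array with 0 outside the mask.
    """

    levels: np.ndarray
    mask: np.ndarray
    roi_name: str
    G: int
    level_width_Gy: float
    reference_max_Gy: float
    grid: Optional[Grid] = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels and mask shapes differ")
        if self.G < 2:
            raise ValueError("need at least 2 grey levels")
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.G):
            raise ValueError("grey levels outside [1, G]")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretise(
    dose: DoseGrid,
    roi: RoiMask,
    G: int = 100,
    range_mode: str = "roi_max",
) -> DiscretisedRoi:
    """Bin absolute dose into ``G`` discrete levels from zero to max dose.

    ``level(d) = min(G, floor(d / d_max * G) + 1)``: bins are left-closed /
    right-open with the top level closed, so ``d = 0 -> 1`` and
    ``d = d_max -> G``.
    """
    if range_mode not in ("roi_max", "global_max"):
        raise ValueError(f"unknown range_mode {range_mode!r}")
    if not dose.grid.same_geometry(roi.grid):
        raise ValueError("dose and ROI are on different grids; resample first")
    if roi.n_voxels == 0:
        raise DiscretisationError(f"ROI {roi.roi_name!r} is empty")
    vals = dose.values[roi.mask]
    d_max = float(vals.max()) if range_mode == "roi_max" else dose.max()
    if d_max <= 0:
        raise DiscretisationError(
            f"all-zero dose in range for ROI {roi.roi_name!r}: no defined grey-level range"
        )
    levels = np.zeros(dose.grid.shape, dtype=np.int32)
    levels[roi.mask] = np.minimum(G, np.floor(vals / d_max * G).astype(np.int64) + 1)
    return DiscretisedRoi(
        levels=levels,
        mask=roi.mask.copy(),
        roi_name=roi.roi_name,
        G=int(G),
        level_width_Gy=d_max / G,
        reference_max_Gy=d_max,
        grid=dose.grid,
    )


def resample_dose(
    dose: DoseGrid, target_grid: Grid, method: str = "linear"
) -> Tuple[DoseGrid, Dict[str, float]]:
    """Trilinear resampling of a dose grid at target voxel centres.

    Target voxels outside the source extent receive 0 Gy and are counted in
    the coverage report ``{"covered_fraction": ..., "n_outside": ...}``.
    """
    if method != "linear":
        raise ValueError("only trilinear ('linear') resampling is supported")
    # continuous index of target voxel centres in the source grid
    idx = [
        (target_grid.voxel_centres(a) - dose.grid.origin_mm[a]) / dose.grid.spacing_mm[a]
        for a in range(3)
    ]
    # inside = within the convex hull of source voxel centres (no extrapolation)
    inside_1d = [(ix >= 0.0) & (ix <= dose.grid.shape[a] - 1.0) for a, ix in enumerate(idx)]
    if not all(arr.any() for arr in inside_1d):
        raise ValueError("target grid is disjoint from the source dose grid")
    coords = np.meshgrid(*idx, indexing="ij")
    values = ndimage.map_coordinates(dose.values, coords, order=1, mode="nearest")
    inside = np.ones(target_grid.shape, dtype=bool)
    for a, arr in enumerate(inside_1d):
        shape = [1, 1, 1]
        shape[a] = -1
        inside &= arr.reshape(shape)
    n_outside = int((~inside).sum())
    report = {
        "covered_fraction": 1.0 - n_outside / inside.size,
        "n_outside": n_outside,
    }
    values[~inside] = 0.0
    np.clip(values, 0.0, None, out=values)
    return DoseGrid(values=values, grid=target_grid), report


def rasterize_contours(
    contours: Union[ContourSet, list],
    grid: Grid,
    roi_name: str = "",
) -> RoiMask:
    """Rasterise planar polygons to a voxel mask by centre inclusion.

    A voxel belongs to the ROI iff its centre lies inside an odd number of
    polygons (even-odd rule) on the nearest slice; polygon orientation is
    irrelevant.  Contour planes must land within half a slice spacing of a
    grid slice.
    """
    if isinstance(contours, ContourSet):
        if roi_name not in contours.rois:
            raise KeyError(f"ROI {roi_name!r} not in contour set")
        polys = contours.rois[roi_name]
    else:
        polys = contours

    mask = np.zeros(grid.shape, dtype=bool)
    if not polys:
        return RoiMask(mask=mask, roi_name=roi_name, grid=grid)

    sz = grid.spacing_mm[0]
    oz = grid.origin_mm[0]
    yc = grid.voxel_centres(1)
    xc = grid.voxel_centres(2)
    xx, yy = np.meshgrid(xc, yc)  # (ny, nx)
    points = np.column_stack([xx.ravel(), yy.ravel()])

    for contour in polys:
        k_float = (contour.plane_z_mm - oz) / sz
        k = int(round(k_float))
        if abs(k_float - k) > 0.5 + 1e-9 or not (0 <= k < grid.shape[0]):
            raise ValueError(
                f"contour plane z={contour.plane_z_mm} mm does not match any grid slice"
            )
        # explicit closing vertex: Path(..., closed=True) drops the last vertex
        ring = np.vstack([contour.vertices[:, :2], contour.vertices[:1, :2]])
        path = MplPath(ring, closed=True)
        inside = path.contains_points(points).reshape(len(yc), len(xc))
        mask[k] ^= inside  # even-odd accumulation across polygons of a slice
    return RoiMask(mask=mask, roi_name=roi_name, grid=grid)
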