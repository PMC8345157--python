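"""Core in-memory containers shared across the package.

Axis convention: all 3D arrays are indexed ``(z, y, x)`` with 0-based indices.
Patient coordinates are in millimetres; ``origin_mm`` is the position of the
*centre* of voxel ``(0, 0, 0)``.  ``spacing_mm`` is stored per axis in the same
``(z, y, x)`` order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import numpy as np

AXIS_ORDER = "zyx"

#: ROI names of a complete synthetic head-and-neck structure set.
STRUCTURE_NAMES = (
    "PTV",
    "parotid_L",
    "parotid_R",
    "spinal_canal",
    "PRV_SC",
    "trachea",
    "RING",
)

#: The six ROIs texture features are extracted from (PRV_SC is QA-only).
EXTRACTION_ROIS = ("PTV", "parotid_L", "parotid_R", "spinal_canal", "trachea", "RING")


@dataclass(frozen=True)
class Grid:
    """Regular 3D voxel grid geometry."""

    shape: Tuple[int, int, int]
    spacing_mm: Tuple[float, float, float]
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing_mm) != 3 or len(self.origin_mm) != 3:
            raise ValueError("Grid requires 3D shape/spacing/origin")
        if any(int(n) < 2 for n in self.shape):
            raise ValueError(f"grid shape must be >= 2 on every axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centres(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(self.shape[axis])

    def coordinate_arrays(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (z, y, x) physical coordinate arrays in mm."""
        z = self.voxel_centres(0)[:, None, None]
        y = self.voxel_centres(1)[None, :, None]
        x = self.voxel_centres(2)[None, None, :]
        return z, y, x

    def same_geometry(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol)
        )


@dataclass
class DoseGrid:
    """A 3D absolute-dose distribution: the dosiomics "image".

    Voxel values are dose in Gy; geometry follows the package-wide (z, y, x)
    convention.
    """

    values: np.ndarray
    grid: Grid
    axis_order: str = AXIS_ORDER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("dose values must be a 3D array")
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError(
                f"dose shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        if self.axis_order != AXIS_ORDER:
            raise ValueError(f"unsupported axis order {self.axis_order!r}")

    @property
    def spacing_mm(self) -> Tuple[float, float, float]:
        return self.grid.spacing_mm

    @property
    def origin_mm(self) -> Tuple[float, float, float]:
        return self.grid.origin_mm

    def max(self) -> float:
        return float(self.values.max())


@dataclass
class RoiMask:
    """Boolean voxel mask of one named structure on a reference grid."""

    mask: np.ndarray
    roi_name: str
    grid: Grid

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if tuple(self.mask.shape) != self.grid.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match grid {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.grid.spacing_mm))


@dataclass
class StructureSet:
    """Named ROI masks sharing one reference grid."""

    reference_grid: Grid
    rois: Dict[str, RoiMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, roi in self.rois.items():
            if not roi.grid.same_geometry(self.reference_grid):
                raise ValueError(f"ROI {name!r} is not on the reference grid")

    def __getitem__(self, name: str) -> RoiMask:
        return self.rois[name]

    def __contains__(self, name: str) -> bool:
        return name in self.rois

    def __iter__(self) -> Iterator[str]:
        return iter(self.rois)

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.rois)

    def validate_synthetic(self) -> None:
        """Check the invariants of a complete synthetic structure set."""
        missing = set(STRUCTURE_NAMES) - set(self.rois)
        if missing:
            raise ValueError(f"missing ROIs: {sorted(missing)}")
        for name, roi in self.rois.items():
            if roi.n_voxels < 2:
                raise ValueError(f"ROI {name!r} has fewer than 2 voxels")
        if np.any(self["PTV"].mask & self["RING"].mask):
            raise ValueError("PTV and RING overlap")
        if np.any(self["spinal_canal"].mask & ~self["PRV_SC"].mask):
            raise ValueError("spinal_canal is not contained in PRV_SC")
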