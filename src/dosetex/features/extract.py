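"""End-to-end feature extraction: dose + masks -> per-ROI feature vectors."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..core import DoseGrid, StructureSet, EXTRACTION_ROIS
from ..preprocessing import DiscretisedRoi, discretise
from .registry import FeatureId, FeatureRegistry, default_registry
from .statistics import stat_features
from .glcm import glcm_features
from .glrlm import runlength_features
from .glszm import sizezone_features

#: ROIs below this voxel count are skipped with an error record.
MIN_ROI_VOXELS = 8


@dataclass
class FeatureVector:
    """Registry-ordered feature values of one (plan, ROI) pair."""

    values: Dict[FeatureId, float]
    provenance: Dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, fid: FeatureId) -> float:
        return self.values[fid]

    def n_undefined(self) -> int:
        return int(sum(1 for v in self.values.values() if not np.isfinite(v)))

    def to_series(self) -> pd.Series:
        index = pd.MultiIndex.from_tuples(
            [(f.family, f.name, f.aggregation) for f in self.values],
            names=["family", "feature", "aggregation"],
        )
        return pd.Series(list(self.values.values()), index=index, dtype=float)


@dataclass
class ExtractionResult:
    """Per-ROI feature vectors plus explicit error records for skipped ROIs."""

    features: Dict[str, FeatureVector]
    errors: Dict[str, str] = field(default_factory=dict)

    def __getitem__(self, roi: str) -> FeatureVector:
        return self.features[roi]

    @property
    def n_values(self) -> int:
        return sum(len(v) for v in self.features.values())


def _crop_to_mask(roi: DiscretisedRoi) -> DiscretisedRoi:
    """Restrict to the mask bounding box (texture matrices are crop-invariant)."""
    idx = np.nonzero(roi.mask)
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    return DiscretisedRoi(
        levels=roi.levels[sl],
        mask=roi.mask[sl],
        roi_name=roi.roi_name,
        G=roi.G,
        level_width_Gy=roi.level_width_Gy,
        reference_max_Gy=roi.reference_max_Gy,
    )


def extract_roi(
    dose: DoseGrid,
    structs: StructureSet,
    roi_name: str,
    registry: Optional[FeatureRegistry] = None,
    G: int = 100,
    range_mode: str = "roi_max",
) -> FeatureVector:
    """Extract the full registry for one ROI.

    Intensity statistics use raw dose in Gy; the texture families use the
    ``G``-level discretisation.
    """
    registry = registry or default_registry()
    roi = structs[roi_name]
    if roi.n_voxels < MIN_ROI_VOXELS:
        raise ValueError(
            f"ROI {roi_name!r} has {roi.n_voxels} voxels (< {MIN_ROI_VOXELS})"
        )
    disc = _crop_to_mask(discretise(dose, roi, G=G, range_mode=range_mode))

    by_family: Dict[str, Dict[str, Dict[str, float]]] = {
        "STAT": {"none": stat_features(dose.values[roi.mask])},
        "GLCM": glcm_features(disc),
        "GLRLM": runlength_features(disc),
        "GLSZM": sizezone_features(disc),
    }
    values = {
        fid: float(by_family[fid.family][fid.aggregation][fid.name]) for fid in registry
    }
    return FeatureVector(
        values=values,
        provenance={
            "roi": roi_name,
            "G": G,
            "range_mode": range_mode,
            "reference_max_Gy": disc.reference_max_Gy,
            "n_voxels": roi.n_voxels,
        },
    )


def extract_all(
    dose: DoseGrid,
    structs: StructureSet,
    registry: Optional[FeatureRegistry] = None,
    G: int = 100,
    range_mode: str = "roi_max",
    rois: Sequence[str] = EXTRACTION_ROIS,
) -> ExtractionResult:
    """Extract the registry from every requested ROI of one plan.

    Deterministic: repeated runs on identical inputs are bit-identical.
    ROIs that are missing or too small yield explicit error records, never a
    silent skip.
    """
    registry = registry or default_registry()
    if not dose.grid.same_geometry(structs.reference_grid):
        raise ValueError("dose and structures are on different grids; resample first")
    features: Dict[str, FeatureVector] = {}
    errors: Dict[str, str] = {}
    for name in rois:
        if name not in structs:
            errors[name] = f"ROI {name!r} not present in the structure set"
            continue
        try:
            features[name] = extract_roi(
                dose, structs, name, registry=registry, G=G, range_mode=range_mode
            )
        except (ValueError,) as exc:
            errors[name] = str(exc)
    return ExtractionResult(features=features, errors=errors)
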