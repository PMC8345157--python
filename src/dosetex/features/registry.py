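"""Feature registry: identity and bookkeeping of the 212-feature set.

The default registry holds 17 intensity statistics (STAT), 100 co-occurrence
features (GLCM: 25 base features x 4 aggregations), 63 run-length features
(GLRLM: 16 x 4 minus one configured entry) and 32 size-zone features
(GLSZM: 16 x 2), for a total of 212.

Which of the 64 run-length entries is dropped to reach 63 is a configuration
item; the default drops ``run_entropy`` under the 2D direction-averaged
aggregation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

FAMILIES = ("STAT", "GLCM", "GLRLM", "GLSZM")

GLCM_AGGREGATIONS = ("2D_avg", "2D_merge", "3D_avg", "3D_merge")
GLRLM_AGGREGATIONS = GLCM_AGGREGATIONS
GLSZM_AGGREGATIONS = ("2D_merge", "3D")

#: The run-length entry removed from the default registry (16 x 4 = 64 -> 63).
DEFAULT_GLRLM_DROP = ("run_entropy", "2D_avg")

REGISTRY_VERSION = "1.0"


@dataclass(frozen=True, order=True)
class FeatureId:
    """Unique identity of one feature: family, IBSI-style name, aggregation."""

    family: str
    name: str
    aggregation: str = "none"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    def __str__(self) -> str:
        return f"{self.family}/{self.name}/{self.aggregation}"


class FeatureRegistry:
    """Ordered collection of :class:`FeatureId` with per-family counts."""

    def __init__(self, feature_ids: Sequence[FeatureId], version: str = REGISTRY_VERSION):
        ids = list(feature_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in registry")
        self._ids: Tuple[FeatureId, ...] = tuple(ids)
        self.version = version

    def __len__(self) -> int:
        return len(self._ids)

    def __iter__(self) -> Iterator[FeatureId]:
        return iter(self._ids)

    def __contains__(self, fid: FeatureId) -> bool:
        return fid in set(self._ids)

    @property
    def feature_ids(self) -> Tuple[FeatureId, ...]:
        return self._ids

    def family_counts(self) -> Dict[str, int]:
        counts = {fam: 0 for fam in FAMILIES}
        for fid in self._ids:
            counts[fid.family] += 1
        return counts

    def family(self, family: str) -> List[FeatureId]:
        return [fid for fid in self._ids if fid.family == family]

    def validate_default_counts(self) -> None:
        """Assert the canonical 17/100/63/32 composition (212 total)."""
        expected = {"STAT": 17, "GLCM": 100, "GLRLM": 63, "GLSZM": 32}
        counts = self.family_counts()
        if counts != expected:
            raise ValueError(f"registry counts {counts} differ from expected {expected}")

    # -- serialisation -----------------------------------------------------

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        doc = {
            "version": self.version,
            "features": [
                {"family": f.family, "name": f.name, "aggregation": f.aggregation}
                for f in self._ids
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "FeatureRegistry":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        doc = json.loads(text)
        ids = [
            FeatureId(item["family"], item["name"], item.get("aggregation", "none"))
            for item in doc["features"]
        ]
        return cls(ids, version=doc.get("version", REGISTRY_VERSION))


def default_registry(
    glrlm_drop: Tuple[str, str] = DEFAULT_GLRLM_DROP,
) -> FeatureRegistry:
    """Build the canonical 212-feature registry."""
    from .statistics import STAT_NAMES
    from .glcm import GLCM_NAMES
    from .glrlm import GLRLM_NAMES
    from .glszm import GLSZM_NAMES

    ids: List[FeatureId] = []
    ids += [FeatureId("STAT", name, "none") for name in STAT_NAMES]
    ids += [
        FeatureId("GLCM", name, agg) for agg in GLCM_AGGREGATIONS for name in GLCM_NAMES
    ]
    dropped = FeatureId("GLRLM", glrlm_drop[0], glrlm_drop[1])
    ids += [
        fid
        for agg in GLRLM_AGGREGATIONS
        for name in GLRLM_NAMES
        if (fid := FeatureId("GLRLM", name, agg)) != dropped
    ]
    ids += [
        FeatureId("GLSZM", name, agg) for agg in GLSZM_AGGREGATIONS for name in GLSZM_NAMES
    ]
    return FeatureRegistry(ids)
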