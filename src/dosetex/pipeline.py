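"""End-to-end study orchestration: generate -> extract -> analyse -> report.

A run produces, under the output directory:

* ``manifest.json``          — software/registry versions, seeds, config hash,
                               per-study bookkeeping counts;
* ``qa.csv``                 — DVH-constraint QA of every generated plan;
* ``features_<study>.csv``   — tidy feature tables (plan, ROI, family,
                               feature, aggregation, value);
* ``cv_<study>.csv``         — per-feature CV records per ROI;
* ``family_summary.csv``     — per-family mean CV and box-plot statistics;
* ``selection.json``         — stable/sensitive sets and Venn membership;
* ``intersections.csv``      — percentage of common features between studies;
* ``software_reproducibility.json`` — max-abs difference of two independent
                               extraction runs on the same dose distribution.

Re-running with the same config and seed reproduces all numbers exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import EXTRACTION_ROIS
from .features import FeatureRegistry, default_registry, extract_all
from .synthetic import (
    Cohort,
    PhantomSpec,
    build_phantom,
    check_constraints,
    generate_cohort,
)
from .variability import (
    FeatureTable,
    compare_extractions,
    family_summary,
    feature_cv_table,
    intersection_summary,
    select_features,
)
from . import rt_io

ALL_DESIGNS = ("reproducibility", "stability", "sensitivity")

#: study tag of the fine / coarse sensitivity resolution
FINE_TAG, COARSE_TAG = "sensitivity_1mm", "sensitivity_2mm"


@dataclass
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    designs: Tuple[str, ...] = ALL_DESIGNS
    rois: Tuple[str, ...] = EXTRACTION_ROIS
    G: int = 100
    range_mode: str = "roi_max"
    stable_th: float = 0.3
    sensitive_ths: Tuple[float, ...] = (1.0, 0.8)
    seed: int = 0
    save_doses: bool = False
    registry: FeatureRegistry = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        unknown = set(self.designs) - set(ALL_DESIGNS)
        if unknown:
            raise ValueError(f"unknown designs: {sorted(unknown)}")
        if self.stable_th <= 0 or any(t <= 0 for t in self.sensitive_ths):
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        phantom = PhantomSpec(**doc.get("phantom", {}))
        kwargs = {k: v for k, v in doc.items() if k != "phantom"}
        for key in ("designs", "rois", "sensitive_ths"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(phantom=phantom, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("registry")
        d["registry_version"] = self.registry.version
        return d

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

@dataclass
class Diagnostic:
    code: str
    message: str


def validate_inputs(
    config: Optional[RunConfig] = None, run_dir: Optional[Path] = None
) -> List[Diagnostic]:
    """Fail-fast checks of a run configuration and/or a cohort directory."""
    diags: List[Diagnostic] = []
    if config is not None:
        counts = config.registry.family_counts()
        expected = {"STAT": 17, "GLCM": 100, "GLRLM": 63, "GLSZM": 32}
        for fam, n in expected.items():
            if counts.get(fam, 0) != n:
                diags.append(
                    Diagnostic(
                        "registry_count_mismatch",
                        f"{fam} has {counts.get(fam, 0)} entries, expected {n}",
                    )
                )
        valid_rois = set(EXTRACTION_ROIS) | {"PRV_SC"}
        for roi in config.rois:
            if roi not in valid_rois:
                diags.append(Diagnostic("unknown_roi", f"unknown ROI name {roi!r}"))
        try:
            _, structs = build_phantom(config.phantom)
            for roi in config.rois:
                if structs[roi].n_voxels < 2:
                    diags.append(
                        Diagnostic("roi_too_small", f"ROI {roi!r} has < 2 voxels")
                    )
        except Exception as exc:  # geometry errors surface as diagnostics
            diags.append(Diagnostic("phantom_geometry", str(exc)))
    if run_dir is not None:
        run_dir = Path(run_dir)
        manifest_path = run_dir / "cohort_manifest.json"
        if not manifest_path.exists():
            diags.append(Diagnostic("missing_manifest", f"no manifest in {run_dir}"))
        else:
            manifest = json.loads(manifest_path.read_text())
            for plan in manifest.get("plans", []):
                f = plan.get("file")
                if f and not (run_dir / f).with_suffix(".npz").exists():
                    diags.append(
                        Diagnostic(
                            "missing_input", f"plan {plan['label']!r} file not found"
                        )
                    )
    return diags


# --------------------------------------------------------------------------
# Cohort persistence
# --------------------------------------------------------------------------

def save_cohort(cohort: Cohort, out_dir: Path, save_doses: bool = True) -> Path:
    """Write the cohort manifest (and optionally dose arrays) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plans = []
    for p in cohort.plans:
        entry = {
            "label": p.label,
            "technique_id": p.technique_id,
            "resolution_mm": p.resolution_mm,
            "seed": p.seed,
        }
        if save_doses:
            stem = f"{p.label}_res{p.resolution_mm:g}mm"
            rt_io.save_internal(p.dose, out_dir / stem)
            entry["file"] = stem
        plans.append(entry)
    manifest = {
        "design": cohort.design,
        "phantom_spec": dataclasses.asdict(cohort.phantom_spec),
        "plans": plans,
    }
    path = out_dir / "cohort_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_cohort(run_dir: Path) -> Cohort:
    """Rebuild a cohort from a manifest directory (structures re-rasterised)."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "cohort_manifest.json").read_text())
    spec_doc = manifest["phantom_spec"]
    spec_doc["voxel_spacing_mm"] = tuple(spec_doc["voxel_spacing_mm"])
    phantom = PhantomSpec(**spec_doc)
    resolutions = sorted({p["resolution_mm"] for p in manifest["plans"]})
    structures = {}
    for res in resolutions:
        _, structs = build_phantom(phantom.with_spacing(res))
        structures[res] = structs
    from .synthetic import PlanRecord, PlanSimSpec

    plans = []
    for p in manifest["plans"]:
        dose = rt_io.load_internal(run_dir / p["file"])
        plans.append(
            PlanRecord(
                label=p["label"],
                technique_id=p["technique_id"],
                resolution_mm=p["resolution_mm"],
                seed=p["seed"],
                spec=PlanSimSpec(technique_id=p["technique_id"], seed=p["seed"]),
                dose=dose,
            )
        )
    return Cohort(
        design=manifest["design"], phantom_spec=phantom, structures=structures, plans=plans
    )


# --------------------------------------------------------------------------
# Study runner
# --------------------------------------------------------------------------

@dataclass
class RunResult:
    config: RunConfig
    out_dir: Path
    tables: Dict[str, Dict[str, FeatureTable]]  # study tag -> roi -> table
    cv_records: Dict[str, pd.DataFrame]  # study tag -> concatenated CV records
    selections: Dict[str, Dict[str, object]]  # roi -> study tag -> SelectionResult
    intersections: pd.DataFrame
    qa: pd.DataFrame
    software_reproducibility: dict
    counts: Dict[str, int]
    manifest: dict


def _extract_cohort_tables(
    cohort: Cohort, config: RunConfig, study_by_resolution: Dict[float, str]
) -> Dict[str, Dict[str, FeatureTable]]:
    """Feature tables per (study tag, ROI) from one cohort."""
    tables: Dict[str, Dict[str, Dict[str, object]]] = {}
    for plan in cohort.plans:
        tag = study_by_resolution[plan.resolution_mm]
        structs = cohort.structures[plan.resolution_mm]
        result = extract_all(
            plan.dose,
            structs,
            registry=config.registry,
            G=config.G,
            range_mode=config.range_mode,
            rois=config.rois,
        )
        if result.errors:
            raise RuntimeError(f"extraction errors for plan {plan.label}: {result.errors}")
        for roi, vec in result.features.items():
            tables.setdefault(tag, {}).setdefault(roi, {})[plan.label] = vec
    return {
        tag: {
            roi: FeatureTable.from_vectors(roi, vectors, study_tag=tag)
            for roi, vectors in by_roi.items()
        }
        for tag, by_roi in tables.items()
    }


def run_study(config: RunConfig, out_dir) -> RunResult:
    """Run the configured study designs end to end and write all reports."""
    t0 = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    diags = validate_inputs(config=config)
    if diags:
        raise ValueError("invalid configuration: " + "; ".join(d.message for d in diags))

    fine = float(config.phantom.voxel_spacing_mm[0])
    tables: Dict[str, Dict[str, FeatureTable]] = {}
    qa_rows: List[dict] = []
    n_distributions = 0

    def qa_cohort(cohort: Cohort) -> None:
        for plan in cohort.plans:
            report = check_constraints(
                plan.dose, cohort.structures[plan.resolution_mm]
            )
            for rec in report.records:
                qa_rows.append(
                    {
                        "design": cohort.design,
                        "plan": plan.label,
                        "resolution_mm": plan.resolution_mm,
                        "structure": rec.structure,
                        "metric": rec.metric,
                        "value": rec.value,
                        "limit": rec.limit,
                        "direction": rec.direction,
                        "passed": rec.passed,
                    }
                )

    wants_stability = "stability" in config.designs
    wants_repro = "reproducibility" in config.designs
    if wants_stability or wants_repro:
        cohort = generate_cohort(config.phantom, "stability", config.seed)
        qa_cohort(cohort)
        n_distributions += len(cohort.plans)
        stab_tables = _extract_cohort_tables(cohort, config, {fine: "stability"})
        if wants_stability:
            tables["stability"] = stab_tables["stability"]
        if wants_repro:
            # the reproducibility study is the 4-plan same-settings subset
            repro_labels = [p.label for p in cohort.plans[:4]]
            tables["reproducibility"] = {
                roi: FeatureTable(
                    roi=roi,
                    data=t.data[repro_labels],
                    study_tag="reproducibility",
                )
                for roi, t in stab_tables["stability"].items()
            }
        if config.save_doses:
            save_cohort(cohort, out_dir / "cohort_stability")

    software_repro: dict = {}
    if "sensitivity" in config.designs:
        cohort = generate_cohort(config.phantom, "sensitivity", config.seed)
        qa_cohort(cohort)
        n_distributions += len(cohort.plans)
        coarse = [r for r in cohort.resolutions if r != fine][0]
        sens_tables = _extract_cohort_tables(
            cohort, config, {fine: FINE_TAG, coarse: COARSE_TAG}
        )
        tables.update(sens_tables)
        if config.save_doses:
            save_cohort(cohort, out_dir / "cohort_sensitivity")

        # software-reproducibility check: re-extract one plan per resolution
        # in a second, independent pass and compare all 2 x 212 features
        first = cohort.plans[0].label
        diffs = {}
        n_compared = 0
        for res, tag in ((fine, FINE_TAG), (coarse, COARSE_TAG)):
            plan = next(p for p in cohort.plans if p.label == first and p.resolution_mm == res)
            rerun = extract_all(
                plan.dose,
                cohort.structures[res],
                registry=config.registry,
                G=config.G,
                range_mode=config.range_mode,
                rois=config.rois[:1],
            )
            table_a = FeatureTable(
                roi=config.rois[0],
                data=tables[tag][config.rois[0]].data[[first]],
                study_tag=tag,
            )
            table_b = FeatureTable.from_vectors(
                config.rois[0], {first: rerun.features[config.rois[0]]}, tag
            )
            cmp = compare_extractions(table_a, table_b)
            diffs[tag] = cmp.max_abs_diff
            n_compared += cmp.n_compared
        software_repro = {
            "plan": first,
            "roi": config.rois[0],
            "n_features_compared": n_compared,
            "max_abs_diff": max(diffs.values()) if diffs else None,
            "per_resolution": diffs,
        }

    # ---------------- analysis ----------------
    registry_size = len(config.registry)
    cv_records: Dict[str, pd.DataFrame] = {}
    selections: Dict[str, Dict[str, object]] = {}
    for tag, by_roi in tables.items():
        frames = []
        for roi, table in by_roi.items():
            records = feature_cv_table(table)
            frames.append(records)
            selections.setdefault(roi, {})[tag] = select_features(
                records,
                stable_th=config.stable_th,
                sensitive_ths=config.sensitive_ths,
                registry_size=registry_size,
            )
        cv_records[tag] = pd.concat(frames, ignore_index=True)

    intersections = intersection_summary(selections, sensitive_th=config.sensitive_ths[0])

    # ---------------- bookkeeping ----------------
    counts = {"features_per_roi_per_plan": registry_size}
    for tag, by_roi in tables.items():
        counts[f"n_values_{tag}"] = sum(t.n_values for t in by_roi.values())
    if FINE_TAG in tables or COARSE_TAG in tables:
        counts["n_values_sensitivity"] = counts.get(f"n_values_{FINE_TAG}", 0) + counts.get(
            f"n_values_{COARSE_TAG}", 0
        )
    counts["n_distributions"] = n_distributions
    counts["n_values_total_unique"] = registry_size * len(config.rois) * n_distributions
    if software_repro:
        counts["n_software_reproducibility_comparisons"] = software_repro[
            "n_features_compared"
        ]

    qa = pd.DataFrame.from_records(qa_rows)

    # ---------------- reports ----------------
    for tag, by_roi in tables.items():
        tidy = []
        for roi, table in by_roi.items():
            stacked = table.data.stack(future_stack=True).reset_index()
            stacked.columns = ["family", "feature", "aggregation", "plan", "value"]
            stacked.insert(0, "ROI", roi)
            tidy.append(stacked)
        pd.concat(tidy, ignore_index=True).to_csv(
            out_dir / f"features_{tag}.csv", index=False
        )
    for tag, records in cv_records.items():
        records.to_csv(out_dir / f"cv_{tag}.csv", index=False)
    if qa_rows:
        qa.to_csv(out_dir / "qa.csv", index=False)
    fam_frames = []
    for tag, records in cv_records.items():
        fs = family_summary(records).reset_index()
        fs.insert(0, "study", tag)
        fam_frames.append(fs)
    if fam_frames:
        pd.concat(fam_frames, ignore_index=True).to_csv(
            out_dir / "family_summary.csv", index=False
        )
    if not intersections.empty:
        intersections.to_csv(out_dir / "intersections.csv")

    selection_doc = {
        roi: {
            tag: {
                "stable_th": sel.stable_th,
                "stable": sorted("/".join(k) for k in sel.stable),
                "stable_percentage": sel.stable_percentage(),
                "sensitive": {
                    str(th): sorted("/".join(k) for k in s)
                    for th, s in sel.sensitive.items()
                },
                "sensitive_percentages": {
                    str(th): sel.sensitive_percentage(th) for th in sel.sensitive
                },
                "n_defined_cv": sel.n_defined_cv,
            }
            for tag, sel in by_study.items()
        }
        for roi, by_study in selections.items()
    }
    (out_dir / "selection.json").write_text(json.dumps(selection_doc, indent=2))
    if software_repro:
        (out_dir / "software_reproducibility.json").write_text(
            json.dumps(software_repro, indent=2)
        )

    manifest = {
        "software_version": __version__,
        "registry_version": config.registry.version,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": counts,
        "sd_convention": "sample (n-1)",
        "runtime_s": round(time.time() - t0, 2),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return RunResult(
        config=config,
        out_dir=out_dir,
        tables=tables,
        cv_records=cv_records,
        selections=selections,
        intersections=intersections,
        qa=qa,
        software_reproducibility=software_repro,
        counts=counts,
        manifest=manifest,
    )
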