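"""Cohort manifest: a JSON index of per-case dose and mask files.

Schema (version 1)::

    {
      "schema_version": 1,
      "protocols": {"A": {"prescription_cGy": 6000.0, "fractions": 30}, ...},
      "models": ["model1", ...],
      "cases": [
        {
          "id": "case_000",
          "protocol": "A",
          "dose": "case_000/dose.nii",
          "gold": {"organ": "case_000/gold/organ.nii", ...},
          "auto": {"model": {"organ": {"path": "..."} |
                             {"status": "failed"|"eroded-away"}}}
        }, ...
      ]
    }

Paths are relative to the manifest's directory.  Grids are loaded lazily;
compatibility is enforced the first time a dose/mask pair is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

from .core_grid import (
    DoseGrid,
    ProtocolSpec,
    StructureMask,
    load_dose_nifti,
    load_mask_nifti,
    save_dose_nifti,
    save_mask_nifti,
)
from .synthetic import Cohort

__all__ = ["ManifestError", "CaseRecord", "LoadedCohort", "write_cohort", "load_cohort"]

SCHEMA_VERSION = 1


class ManifestError(ValueError):
    """Structural problem in a cohort manifest."""


@dataclass
class CaseRecord:
    case_id: str
    protocol: ProtocolSpec
    dose_path: Path
    gold_paths: Dict[str, Path]
    # model -> organ -> path, or None when the manifest marks it failed
    auto_paths: Dict[str, Dict[str, Path]]
    auto_status: Dict[str, Dict[str, str]]

    def load_dose(self) -> DoseGrid:
        return load_dose_nifti(self.dose_path)

    def load_gold(self) -> Dict[str, StructureMask]:
        return {organ: load_mask_nifti(p) for organ, p in self.gold_paths.items()}

    def load_auto(self, model: str) -> Dict[str, StructureMask]:
        out: Dict[str, StructureMask] = {}
        for organ, status in self.auto_status[model].items():
            if status == "ok":
                out[organ] = load_mask_nifti(self.auto_paths[model][organ])
            else:
                mask = load_mask_nifti(self.gold_paths[organ])
                out[organ] = StructureMask.absent(mask.header, status=status)
        return out


@dataclass
class LoadedCohort:
    manifest_path: Path
    protocols: Dict[str, ProtocolSpec]
    models: List[str]
    cases: List[CaseRecord]


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a simulated cohort as a NIfTI tree plus ``manifest.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    protocols = {}
    case_entries = []
    for case in cohort.cases:
        protocols[case.protocol.name] = {
            "prescription_cGy": case.protocol.prescription_cGy,
            "fractions": case.protocol.fractions,
        }
        case_dir = out_dir / case.case_id
        (case_dir / "gold").mkdir(parents=True, exist_ok=True)
        dose_rel = f"{case.case_id}/dose.nii"
        save_dose_nifti(case.dose, out_dir / dose_rel)
        gold_entry = {}
        for organ, mask in sorted(case.gold.items()):
            rel = f"{case.case_id}/gold/{organ}.nii"
            save_mask_nifti(mask, out_dir / rel)
            gold_entry[organ] = rel
        auto_entry: Dict[str, dict] = {}
        for model in cohort.models:
            (case_dir / model).mkdir(exist_ok=True)
            auto_entry[model] = {}
            for organ, mask in sorted(case.auto[model].items()):
                if mask.present:
                    rel = f"{case.case_id}/{model}/{organ}.nii"
                    save_mask_nifti(mask, out_dir / rel)
                    auto_entry[model][organ] = {"path": rel}
                else:
                    auto_entry[model][organ] = {"status": mask.status}
        case_entries.append(
            {
                "id": case.case_id,
                "protocol": case.protocol.name,
                "dose": dose_rel,
                "gold": gold_entry,
                "auto": auto_entry,
            }
        )
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "protocols": protocols,
        "models": list(cohort.models),
        "cases": case_entries,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def load_cohort(manifest_path: str | Path) -> LoadedCohort:
    """Validate and index a manifest; volumes themselves load lazily."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        raw = json.load(fh)
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ManifestError(f"unsupported schema version {version!r}")
    protocols = {
        name: ProtocolSpec(name, float(p["prescription_cGy"]), int(p["fractions"]))
        for name, p in raw["protocols"].items()
    }
    models = list(raw.get("models", []))
    cases: List[CaseRecord] = []
    seen_ids = set()
    for entry in raw["cases"]:
        cid = entry["id"]
        if cid in seen_ids:
            raise ManifestError(f"duplicate case id {cid!r}")
        seen_ids.add(cid)
        if entry["protocol"] not in protocols:
            raise ManifestError(f"case {cid}: unknown protocol {entry['protocol']!r}")
        dose_path = root / entry["dose"]
        if not dose_path.exists():
            raise ManifestError(f"case {cid}: missing dose file {dose_path}")
        gold_paths = {}
        for organ, rel in entry["gold"].items():
            p = root / rel
            if not p.exists():
                raise ManifestError(f"case {cid}, organ {organ}: missing gold file {p}")
            gold_paths[organ] = p
        auto_paths: Dict[str, Dict[str, Path]] = {}
        auto_status: Dict[str, Dict[str, str]] = {}
        for model, organs in entry["auto"].items():
            auto_paths[model] = {}
            auto_status[model] = {}
            for organ, rec in organs.items():
                if organ not in gold_paths:
                    raise ManifestError(
                        f"case {cid}, model {model}: auto organ {organ!r} has no gold"
                    )
                if "path" in rec:
                    p = root / rec["path"]
                    if not p.exists():
                        raise ManifestError(
                            f"case {cid}, model {model}, organ {organ}: "
                            f"missing auto file {p} (no failed marker)"
                        )
                    auto_paths[model][organ] = p
                    auto_status[model][organ] = "ok"
                elif "status" in rec:
                    auto_status[model][organ] = rec["status"]
                else:
                    raise ManifestError(
                        f"case {cid}, model {model}, organ {organ}: "
                        "auto entry needs 'path' or 'status'"
                    )
        cases.append(
            CaseRecord(
                case_id=cid,
                protocol=protocols[entry["protocol"]],
                dose_path=dose_path,
                gold_paths=gold_paths,
                auto_paths=auto_paths,
                auto_status=auto_status,
            )
        )
    return LoadedCohort(
        manifest_path=manifest_path, protocols=protocols, models=models, cases=cases
    )
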