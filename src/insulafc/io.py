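"""File-format adapters: NIfTI volumes/runs, TSV tables, JSON manifests.

All cohort artifacts round-trip losslessly within storage precision
(runs are stored as float32 NIfTI-1 images with the grid affine).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import (
    CONFOUND_COLUMNS,
    BOLDRun,
    Cohort,
    ConfoundTable,
    PhenotypeRecord,
)
from .grid import GridSpec

__all__ = [
    "FormatError",
    "save_volume",
    "load_volume",
    "save_run",
    "load_run",
    "save_confounds",
    "load_confounds",
    "save_phenotypes",
    "load_phenotypes",
    "write_cohort",
    "read_cohort",
    "file_digest",
]

MANIFEST_NAME = "manifest.json"
PHENOTYPE_COLUMNS = ["subject_id", "group", "at_hours_per_week", "elo_points",
                     "ds_seconds", "game_type"]


class FormatError(ValueError):
    """Malformed input file (header, columns, or manifest reference)."""


def _grid_to_dict(grid: GridSpec) -> dict:
    return {
        "dims": list(grid.dims),
        "voxel_size_mm": list(grid.voxel_size_mm),
        "tr_seconds": grid.tr_seconds,
        "n_volumes": grid.n_volumes,
    }


def _grid_from_dict(d: dict) -> GridSpec:
    return GridSpec(
        dims=tuple(d["dims"]),
        voxel_size_mm=tuple(d["voxel_size_mm"]),
        tr_seconds=d["tr_seconds"],
        n_volumes=d["n_volumes"],
    )


def save_volume(data: np.ndarray, grid: GridSpec, path) -> None:
    """Write a 3D or 4D array as NIfTI-1 with the grid affine."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    img.header.set_zooms((*grid.voxel_size_mm, grid.tr_seconds)[: data.ndim])
    nib.save(img, str(path))


def load_volume(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    return np.asarray(nib.load(str(path)).get_fdata())


def save_run(run: BOLDRun, path) -> None:
    save_volume(run.data, run.grid, path)


def load_run(path, grid: GridSpec, subject_id: str) -> BOLDRun:
    data = load_volume(path)
    if data.shape != grid.shape4d:
        raise FormatError(
            f"{path}: data shape {data.shape} does not match manifest grid {grid.shape4d}"
        )
    return BOLDRun(subject_id=subject_id, data=data, grid=grid)


def save_confounds(conf: ConfoundTable, path) -> None:
    conf.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_confounds(path, subject_id: str) -> ConfoundTable:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in CONFOUND_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: confound table missing columns {missing}")
    return ConfoundTable(subject_id=subject_id, data=table[CONFOUND_COLUMNS])


def save_phenotypes(records: list[PhenotypeRecord], path) -> None:
    rows = []
    for rec in records:
        row = {c: getattr(rec, c) for c in PHENOTYPE_COLUMNS}
        if rec.gmv_mm3:
            row.update({f"gmv_{k}": v for k, v in rec.gmv_mm3.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_phenotypes(path) -> list[PhenotypeRecord]:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: phenotype table missing columns {missing}")
    gmv_cols = [c for c in table.columns if c.startswith("gmv_")]
    records = []
    for row in table.to_dict("records"):
        gmv = {c[len("gmv_"):]: float(row[c]) for c in gmv_cols
               if pd.notna(row[c])} or None
        records.append(PhenotypeRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            at_hours_per_week=float(row["at_hours_per_week"]),
            elo_points=float(row["elo_points"]),
            ds_seconds=float(row["ds_seconds"]),
            game_type=str(row["game_type"]),
            gmv_mm3=gmv,
        ))
    return records


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_cohort(cohort: Cohort, directory) -> dict:
    """Write runs (NIfTI), confound/phenotype/ground-truth TSVs and a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    subjects = []
    for run, conf in zip(cohort.runs, cohort.confounds):
        bold_name = f"{run.subject_id}_bold.nii.gz"
        conf_name = f"{run.subject_id}_confounds.tsv"
        save_run(run, directory / bold_name)
        save_confounds(conf, directory / conf_name)
        group = next(p.group for p in cohort.phenotypes if p.subject_id == run.subject_id)
        subjects.append({"subject_id": run.subject_id, "group": group,
                         "bold": bold_name, "confounds": conf_name})
    manifest: dict = {
        "grid": _grid_to_dict(cohort.config.grid),
        "seed": cohort.config.seed,
        "subjects": subjects,
    }
    if cohort.phenotypes:
        save_phenotypes(cohort.phenotypes, directory / "phenotype.tsv")
        manifest["phenotype"] = "phenotype.tsv"
    if len(cohort.ground_truth):
        cohort.ground_truth.to_csv(directory / "ground_truth.tsv", sep="\t",
                                   index=False, float_format="%.10g")
        manifest["ground_truth"] = "ground_truth.tsv"
    with open(directory / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_cohort(directory, config=None) -> Cohort:
    """Load a cohort written by :func:`write_cohort`, validating the manifest
    before any volume is read."""
    from .cohort import CohortConfig

    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise FormatError(f"no {MANIFEST_NAME} in {directory}")
    manifest = json.loads(manifest_path.read_text())
    grid = _grid_from_dict(manifest["grid"])
    referenced = [s["bold"] for s in manifest["subjects"]]
    referenced += [s["confounds"] for s in manifest["subjects"]]
    referenced += [manifest[k] for k in ("phenotype", "ground_truth") if k in manifest]
    missing = [name for name in referenced if not (directory / name).exists()]
    if missing:
        raise FormatError(f"manifest references absent files: {missing}")

    runs, confounds = [], []
    for sub in manifest["subjects"]:
        runs.append(load_run(directory / sub["bold"], grid, sub["subject_id"]))
        confounds.append(load_confounds(directory / sub["confounds"], sub["subject_id"]))
    phenotypes = (load_phenotypes(directory / manifest["phenotype"])
                  if "phenotype" in manifest else [])
    truth = (pd.read_csv(directory / manifest["ground_truth"], sep="\t")
             if "ground_truth" in manifest else pd.DataFrame())
    if config is None:
        config = CohortConfig(
            n_expert=sum(s["group"] == "expert" for s in manifest["subjects"]),
            n_amateur=sum(s["group"] == "amateur" for s in manifest["subjects"]),
            grid=grid,
            seed=manifest.get("seed", 0),
        )
    return Cohort(runs=runs, confounds=confounds, phenotypes=phenotypes,
                  ground_truth=truth, config=config)
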