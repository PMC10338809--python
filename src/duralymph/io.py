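"""NIfTI/JSON/CSV input-output for dynamic series and cohort tables.

A series is stored as one 4-D NIfTI volume plus a brain-mask NIfTI and a
JSON sidecar holding the realized acquisition times (minutes), the ROI seed
voxel, the generation seed, and — for synthetic subjects — the ground-truth
kinetic parameters.  Arrays round-trip bit-exactly (float64 on disk).

In-memory arrays are indexed ``(time, slice, row, col)`` with 0-based voxel
coordinates ``(slice, row, col)``; on disk the NIfTI data axes are
``(col, row, slice, time)`` with the in-plane/slice voxel sizes of the
dynamic protocol in the affine.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .errors import InputError
from .kinetics import KineticTruth
from .phantom import DynamicSeries

_AFFINE = np.diag([0.52, 0.52, 3.0, 1.0])


def _series_paths(path: Path) -> tuple[Path, Path, Path]:
    """Map a base path (or any of the three component paths) to the trio."""
    name = path.name
    for ext in (".json", ".gz", ".nii"):
        if name.endswith(ext):
            name = name[: -len(ext)]
    for suffix in ("_series", "_mask", "_sidecar"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return (
        path.parent / f"{name}_series.nii.gz",
        path.parent / f"{name}_mask.nii.gz",
        path.parent / f"{name}_sidecar.json",
    )


def write_series(series: DynamicSeries, path) -> dict[str, Path]:
    """Write one subject's series, mask and sidecar under a base path.

    ``path`` is a base name (directory/subject); three files are produced:
    ``<base>_series.nii.gz``, ``<base>_mask.nii.gz``, ``<base>_sidecar.json``.
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    series_path, mask_path, sidecar_path = _series_paths(base)

    # memory order (t, slice, row, col) -> NIfTI (col, row, slice, t)
    on_disk = np.transpose(series.data, (3, 2, 1, 0)).astype(np.float64)
    nib.save(nib.Nifti1Image(on_disk, _AFFINE), str(series_path))
    mask_disk = np.transpose(series.brain_mask, (2, 1, 0)).astype(np.uint8)
    nib.save(nib.Nifti1Image(mask_disk, _AFFINE), str(mask_path))

    sidecar = {
        "subject_id": series.subject_id,
        "times_min": [float(t) for t in series.times],
        "roi_seed": [int(v) for v in series.roi_seed],
        "seed": series.seed,
        "truth": asdict(series.truth) if series.truth is not None else None,
        "axes": "(slice, row, col), 0-based; NIfTI data stored (col, row, slice, time)",
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return {"series": series_path, "mask": mask_path, "sidecar": sidecar_path}


def read_series(path) -> DynamicSeries:
    """Read a series written by :func:`write_series` (base path or any of
    the three file paths)."""
    series_path, mask_path, sidecar_path = _series_paths(Path(path))
    for p in (series_path, mask_path, sidecar_path):
        if not p.exists():
            raise InputError(f"missing series component: {p}")
    sidecar = json.loads(sidecar_path.read_text())
    data = np.transpose(np.asarray(nib.load(str(series_path)).dataobj, dtype=np.float64), (3, 2, 1, 0))
    mask = np.transpose(np.asarray(nib.load(str(mask_path)).dataobj), (2, 1, 0)).astype(bool)
    truth = KineticTruth(**sidecar["truth"]) if sidecar.get("truth") else None
    return DynamicSeries(
        data=data,
        times=np.asarray(sidecar["times_min"], dtype=np.float64),
        brain_mask=mask,
        roi_seed=tuple(sidecar["roi_seed"]),
        subject_id=sidecar.get("subject_id", "sub-001"),
        truth=truth,
        seed=sidecar.get("seed"),
    )


COVARIATE_COLUMNS = [
    "subject_id", "age", "bmi", "disease_duration", "edss", "t2lv_ml", "bpf", "phenotype",
]


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Cohort covariate table (one row per subject)."""
    rows = []
    for rec in records:
        c = rec.covariates
        rows.append(
            {
                "subject_id": rec.subject_id,
                "age": c.age,
                "bmi": c.bmi,
                "disease_duration": c.disease_duration,
                "edss": c.edss,
                "t2lv_ml": c.t2lv,
                "bpf": c.bpf,
                "phenotype": c.phenotype,
            }
        )
    return pd.DataFrame(rows, columns=COVARIATE_COLUMNS)


def write_cohort_csv(records: list[SubjectRecord], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort_to_frame(records).to_csv(path, index=False)
    return path


def write_curve_csv(curve, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    curve.to_frame().to_csv(path, index=False)
    return path


def read_curve_csv(path):
    from .roi import TimeIntensityCurve

    return TimeIntensityCurve.from_frame(pd.read_csv(path))
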