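"""Cohort persistence: CSV tables, NIfTI-1 volumes/masks, JSON manifest."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .simulate import BlotPanel, ImagingStudy, PatientRecord

CLINICAL_CSV = "clinical.csv"
BLOTS_CSV = "blots.csv"
MANIFEST_JSON = "manifest.json"


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def persist_cohort(
    records: list[PatientRecord],
    blots: list[BlotPanel],
    studies: list[ImagingStudy] | None,
    out_dir: str | Path,
) -> dict:
    """Write the cohort to disk; returns the manifest.

    Clinical and blot tables as CSV (floats at full repr precision, so a
    round-trip read reproduces values exactly), one gzipped NIfTI-1 file
    per volume and mask with the voxel spacing on the affine diagonal,
    and a JSON manifest tying files to patient ids.
    """
    ids_clin = [r.patient_id for r in records]
    ids_blot = [b.patient_id for b in blots]
    if set(ids_clin) != set(ids_blot):
        raise ConsistencyError("clinical and blot tables disagree on patient ids")
    if studies:
        extra = {s.patient_id for s in studies} - set(ids_clin)
        if extra:
            raise ConsistencyError(f"imaging studies for unknown patients: {sorted(extra)}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([asdict(r) for r in records]).to_csv(out / CLINICAL_CSV, index=False)
    pd.DataFrame([asdict(b) for b in blots]).to_csv(out / BLOTS_CSV, index=False)

    manifest: dict = {"patients": {}, "n_patients": len(records)}
    for pid in ids_clin:
        manifest["patients"][pid] = {"imaging": None}
    for study in studies or []:
        study.validate()
        pid = study.patient_id
        vol_file = f"{pid}_volume.nii.gz"
        muscle_file = f"{pid}_muscle.nii.gz"
        lesion_files = [f"{pid}_lesion{k}.nii.gz" for k in range(len(study.lesion_masks))]
        aff = _affine(study.voxel_spacing_mm)
        nib.save(nib.Nifti1Image(study.volume.astype(np.float64), aff), out / vol_file)
        nib.save(
            nib.Nifti1Image(study.muscle_mask.astype(np.uint8), aff), out / muscle_file
        )
        for fname, lesion in zip(lesion_files, study.lesion_masks):
            nib.save(nib.Nifti1Image(lesion.astype(np.uint8), aff), out / fname)
        manifest["patients"][pid] = {
            "imaging": {
                "volume": vol_file,
                "muscle": muscle_file,
                "lesions": lesion_files,
                "voxel_spacing_mm": list(study.voxel_spacing_mm),
            }
        }
    (out / MANIFEST_JSON).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_cohort(
    in_dir: str | Path,
) -> tuple[list[PatientRecord], list[BlotPanel], list[ImagingStudy]]:
    """Read back a persisted cohort; inverse of :func:`persist_cohort`."""
    src = Path(in_dir)
    clin = pd.read_csv(src / CLINICAL_CSV, float_precision="round_trip")
    blot = pd.read_csv(src / BLOTS_CSV, float_precision="round_trip")
    if set(clin["patient_id"]) != set(blot["patient_id"]):
        raise ConsistencyError("clinical and blot tables disagree on patient ids")
    records = [
        PatientRecord(
            patient_id=str(r.patient_id),
            arm=str(r.arm),
            line=int(r.line),
            tissue_tps=str(r.tissue_tps),
            durable_response=str(r.durable_response),
            early_response=str(r.early_response),
            lesion_size_change=float(r.lesion_size_change),
            pfs_months=float(r.pfs_months),
            os_months=float(r.os_months),
            pfs_event=bool(r.pfs_event),
            os_event=bool(r.os_event),
        )
        for r in clin.itertuples()
    ]
    blots = [
        BlotPanel(
            patient_id=str(b.patient_id),
            pdl1_t1=float(b.pdl1_t1),
            cd9_t1=float(b.cd9_t1),
            pdl1_t2=float(b.pdl1_t2),
            cd9_t2=float(b.cd9_t2),
        )
        for b in blot.itertuples()
    ]

    manifest_path = src / MANIFEST_JSON
    studies: list[ImagingStudy] = []
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        for pid, entry in manifest["patients"].items():
            imaging = entry.get("imaging")
            if imaging is None:
                continue
            for key in ("volume", "muscle"):
                if not (src / imaging[key]).exists():
                    raise ConsistencyError(f"missing {key} file for patient {pid}")
            volume = np.asarray(nib.load(src / imaging["volume"]).dataobj, dtype=np.float64)
            muscle = np.asarray(nib.load(src / imaging["muscle"]).dataobj).astype(bool)
            lesions = []
            for fname in imaging["lesions"]:
                if not (src / fname).exists():
                    raise ConsistencyError(f"missing lesion file {fname} for patient {pid}")
                lesions.append(np.asarray(nib.load(src / fname).dataobj).astype(bool))
            studies.append(
                ImagingStudy(
                    patient_id=pid,
                    volume=volume,
                    lesion_masks=lesions,
                    muscle_mask=muscle,
                    voxel_spacing_mm=tuple(imaging["voxel_spacing_mm"]),
                )
            )
    return records, blots, studies
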